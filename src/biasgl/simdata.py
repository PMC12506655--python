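"""Synthetic-data generator emulating an ancient-DNA admixture study.

The scenario: four populations related as (S1, ((S2, T), S3)), where S1 is
an outgroup used for SNP ascertainment, S2 and S3 are the two admixture
sources, and the target T receives a single pulse of proportion ``f`` from
S3.  Split depths are fixed fractions of the deepest split ``t123``:
``t23 = 0.5 * t123`` (split of S3 from the (S2, T) lineage) and
``t_T,S2 = 0.2 * t123``.  Allele-frequency evolution along each branch is
modelled with Balding-Nichols beta drift parameterized by
``F = 1 - exp(-t / (2 Ne))``, which preserves the drift scalings of the
coalescent topology while running in milliseconds; sites are independent
(no linkage), which matches the site-wise estimators evaluated here.

Reads are short aDNA-like fragments: log-normal lengths (location drawn
uniformly in [3.3, 3.8] per individual, scale 0.2, minimum 30 bp), placed
on a random ancestral sequence of 41% GC, with per-base phred-driven
sequencing error and site coverage Poisson in the target depth.  Only
transversion polymorphisms are produced.  Mapping bias is a parametric
read-loss process: a mapper that keeps every reference-carrying read and
drops each alternative-carrying read independently with probability
``beta`` — the tunable stand-in for the mismatch-driven losses of a real
short-read mapper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from biasgl.bias_estim import collect_observations
from biasgl.reads import AlignedRead, FlippedRead, ReadObservation
from biasgl.snp_panel import SnpPanel, SnpSite, write_panel

POPULATIONS = ("S1", "S2", "S3", "T")

# Transversion partners: purine -> pyrimidines and vice versa.
_TRANSVERSION_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class SimScenario:
    """All parameters of one simulated study.

    Defaults follow the simulated study design this generator emulates:
    ``Ne`` 10,000; 21 diploid individuals per population; an admixture
    pulse 50 generations ago; outgroup ascertainment at MAF >= 10%;
    fragment location drawn per individual from U(3.3, 3.8) with scale 0.2
    and a 30 bp minimum; 41% GC ancestral sequence; phred-30 base errors.
    ``t123`` defaults to 20,000 generations (divergent conspecific
    populations); ``depth`` to 0.5x, the sparse end of the depths studied.
    ``n_sites`` is the post-ascertainment panel size, desk-scaled by
    default.  ``beta`` is the alternative-read loss probability of the
    parametric biased mapper; 0 disables bias.
    """

    t123: float = 20_000.0
    ne: float = 10_000.0
    f: float = 0.1
    pulse_age: float = 50.0
    n_ind: int = 21
    n_sites: int = 2_000
    depth: float = 0.5
    frag_loc: Optional[float] = None  # None: per-individual U(3.3, 3.8)
    frag_loc_range: tuple[float, float] = (3.3, 3.8)
    frag_scale: float = 0.2
    frag_min: int = 30
    gc: float = 0.41
    beta: float = 0.0
    error_q: int = 30
    mapq: int = 60
    maf_min: float = 0.1
    reference_pop: Optional[str] = None
    ascertainment_oversample: float = 4.0
    site_spacing: int = 200
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("admixture proportion f must be in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        if self.frag_scale <= 0 or (self.frag_loc is not None and self.frag_loc <= 0):
            raise ValueError("fragment parameters must be positive")

    @property
    def t23(self) -> float:
        return 0.5 * self.t123

    @property
    def t_t_s2(self) -> float:
        return 0.2 * self.t123

    def drift_f(self, t: float) -> float:
        """Balding-Nichols F for a branch of ``t`` generations."""
        return 1.0 - float(np.exp(-t / (2.0 * self.ne)))


@dataclass
class SiteFrequencies:
    """Per-site true reference-allele frequencies (pre- or post-ascertainment)."""

    positions: np.ndarray  # 1-based, sorted
    ref: np.ndarray  # ancestral/reference base per site
    alt: np.ndarray  # derived transversion partner
    freqs: dict[str, np.ndarray]  # population -> ref-allele frequency

    def __len__(self) -> int:
        return len(self.positions)

    def subset(self, idx: np.ndarray) -> "SiteFrequencies":
        return SiteFrequencies(
            positions=self.positions[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            freqs={k: v[idx] for k, v in self.freqs.items()},
        )

    def to_panel(self, chrom: str) -> SnpPanel:
        sites = tuple(
            SnpSite(chrom, int(p), str(r), str(a))
            for p, r, a in zip(self.positions, self.ref, self.alt)
        )
        return SnpPanel(sites, transversions_only=True)


@dataclass
class SimTruth:
    """Ground truth of one bundle: frequencies, genotypes, admixture."""

    freqs: SiteFrequencies
    genotypes: dict[str, np.ndarray]  # pop -> (n_ind, n_sites) ref dosage
    admixture: dict[str, float]  # individual -> true admixture proportion


def simulate_ancestral_sequence(
    length: int, gc: float = 0.41, rng: Union[int, np.random.Generator] = 0
) -> np.ndarray:
    """Random i.i.d. sequence with P(G) = P(C) = gc/2, P(A) = P(T) = (1-gc)/2.

    Returned as a numpy array of single characters for cheap slicing.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=length, p=probs)


def _truncated_beta(rng: np.random.Generator, a: float, b: float, size: int,
                    lo: float, hi: float) -> np.ndarray:
    out = rng.beta(a, b, size=size)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def _bn_drift(rng: np.random.Generator, p: np.ndarray, f_drift: float) -> np.ndarray:
    """One Balding-Nichols drift step: child ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    if f_drift <= 0.0:
        return p.copy()
    scale = (1.0 - f_drift) / f_drift
    p_safe = np.clip(p, 1e-9, 1.0 - 1e-9)
    return rng.beta(p_safe * scale, (1.0 - p_safe) * scale)


def simulate_frequencies(
    scenario: SimScenario,
    rng: Union[int, np.random.Generator, None] = None,
    n_sites: Optional[int] = None,
) -> SiteFrequencies:
    """True per-population reference-allele frequencies at raw candidate sites.

    The ancestral frequency spectrum is Beta(0.5, 0.5) truncated to
    (0.05, 0.95) — a U-shaped spectrum compatible with downstream
    common-variant ascertainment.  Each branch of the topology applies one
    Balding-Nichols step with its own F; the target's pre-pulse frequency
    follows the S2 lineage, and the pulse mixes in S3's present-day
    frequency: ``p_T = f * p_S3 + (1 - f) * p_T,pre``.
    """
    rng = np.random.default_rng(scenario.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    n = n_sites if n_sites is not None else int(
        round(scenario.n_sites * scenario.ascertainment_oversample)
    )
    positions = np.arange(1, n + 1) * scenario.site_spacing
    seq = simulate_ancestral_sequence(int(positions[-1]) + scenario.site_spacing,
                                      scenario.gc, rng)
    ref = seq[positions - 1]
    partners = np.array([_TRANSVERSION_PARTNERS[b] for b in ref])
    pick = rng.integers(2, size=n)
    alt = np.array([p[i] for p, i in zip(partners, pick)])

    p0 = _truncated_beta(rng, 0.5, 0.5, n, 0.05, 0.95)
    # Branch drift amounts (generations); present is time 0.
    p_s1 = _bn_drift(rng, p0, scenario.drift_f(scenario.t123))
    p_anc23 = _bn_drift(rng, p0, scenario.drift_f(scenario.t123 - scenario.t23))
    p_s3 = _bn_drift(rng, p_anc23, scenario.drift_f(scenario.t23))
    p_anc2t = _bn_drift(rng, p_anc23, scenario.drift_f(scenario.t23 - scenario.t_t_s2))
    p_s2 = _bn_drift(rng, p_anc2t, scenario.drift_f(scenario.t_t_s2))
    # The target's pre-pulse frequency follows the S2 lineage: the recent
    # T/S2 divergence is collapsed so that post-pulse T is an *exact*
    # mixture of the present-day source frequencies.  This keeps the
    # supervised admixture model correctly specified and isolates mapping
    # bias from lineage-specific drift the estimators cannot account for.
    p_t_pre = p_s2
    p_t = scenario.f * p_s3 + (1.0 - scenario.f) * p_t_pre

    freqs = {"S1": p_s1, "S2": p_s2, "S3": p_s3, "T": p_t}
    if scenario.reference_pop is not None:
        # The mapping reference is a haplotype sampled from a population
        # (as when one sequenced genome serves as the reference): at each
        # site the reference carries that population's ancestral allele
        # with probability equal to its frequency there.  Where the
        # sampled haplotype carries the derived allele, the ref/alt
        # labels (and all frequencies) swap — reference alleles then tend
        # to be the locally major allele, as in real panels.
        if scenario.reference_pop not in freqs:
            raise ValueError(f"unknown reference_pop {scenario.reference_pop!r}")
        ref_is_ancestral = rng.random(n) < freqs[scenario.reference_pop]
        swap = ~ref_is_ancestral
        ref[swap], alt[swap] = alt[swap], ref[swap].copy()
        freqs = {pop: np.where(swap, 1.0 - p, p) for pop, p in freqs.items()}

    return SiteFrequencies(
        positions=positions,
        ref=ref,
        alt=alt,
        freqs=freqs,
    )


def ascertain_sites(
    freqs: SiteFrequencies,
    scenario: SimScenario,
    rng: Union[int, np.random.Generator],
    maf_min: Optional[float] = None,
    n_keep: Optional[int] = None,
) -> np.ndarray:
    """Indices of sites passing outgroup ascertainment, thinned to ``n_keep``.

    Ascertainment draws a sample of ``2 * n_ind`` S1 chromosomes per site
    and requires a sample minor-allele frequency of at least ``maf_min``;
    survivors are thinned uniformly at random.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    maf_min = scenario.maf_min if maf_min is None else maf_min
    n_keep = scenario.n_sites if n_keep is None else n_keep
    n_chrom = 2 * scenario.n_ind
    counts = rng.binomial(n_chrom, freqs.freqs["S1"])
    maf = np.minimum(counts, n_chrom - counts) / n_chrom
    survivors = np.flatnonzero(maf >= maf_min)
    if survivors.size == 0:
        raise ValueError(
            "no sites survive outgroup ascertainment; increase n_sites or relax maf_min"
        )
    if survivors.size <= n_keep:
        if survivors.size < n_keep:
            warnings.warn(
                f"only {survivors.size} sites survive ascertainment "
                f"(requested {n_keep}); keeping all survivors"
            )
        return survivors
    keep = rng.choice(survivors, size=n_keep, replace=False)
    return np.sort(keep)


def simulate_genotypes(
    freqs: SiteFrequencies,
    scenario: SimScenario,
    rng: Union[int, np.random.Generator],
    populations: Sequence[str] = POPULATIONS,
) -> dict[str, np.ndarray]:
    """Draw per-individual reference-allele dosages ~ Binomial(2, p) (HWE)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return {
        pop: rng.binomial(2, freqs.freqs[pop], size=(scenario.n_ind, len(freqs)))
        for pop in populations
    }


def simulate_fragments(
    scenario: SimScenario,
    n: int,
    rng: Union[int, np.random.Generator],
    loc: Optional[float] = None,
) -> np.ndarray:
    """Log-normal fragment lengths, rejecting those below ``frag_min``.

    With the default location range the analytic (untruncated) mean length
    lies between exp(3.3 + 0.02) ~ 27.7 bp and exp(3.8 + 0.02) ~ 45.6 bp.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if loc is None:
        loc = scenario.frag_loc if scenario.frag_loc is not None else float(
            rng.uniform(*scenario.frag_loc_range)
        )
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = rng.lognormal(loc, scenario.frag_scale, size=max(n - filled, 16))
        draw = draw[draw >= scenario.frag_min].astype(int)
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def simulate_reads(
    dosages: np.ndarray,
    freqs: SiteFrequencies,
    scenario: SimScenario,
    rng: Union[int, np.random.Generator],
    sequence: np.ndarray,
    individual: str = "ind",
    frag_loc: Optional[float] = None,
) -> list[AlignedRead]:
    """Sequencing reads for one individual over the panel sites.

    Site-centric generation: per site the read count is Poisson(depth);
    each read copies one of the two chromosomes uniformly — so at every
    panel site the read covers, it carries the reference allele with
    probability dosage/2 independently (sites are unlinked).  Per-base
    sequencing errors flip to one of the three other bases uniformly with
    the phred-``error_q`` probability.  Alternative-carrying reads at the
    focal site are then lost with probability ``beta``, the generation-side
    arm of the parametric mapping-bias process.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if frag_loc is None:
        frag_loc = scenario.frag_loc if scenario.frag_loc is not None else float(
            rng.uniform(*scenario.frag_loc_range)
        )
    n_sites = len(freqs)
    if dosages.shape != (n_sites,):
        raise ValueError(f"dosages must have shape ({n_sites},), got {dosages.shape}")
    err = 10.0 ** (-scenario.error_q / 10.0)
    genome_len = len(sequence)
    bases = "ACGT"
    pos_arr = freqs.positions
    reads: list[AlignedRead] = []
    counts = rng.poisson(scenario.depth, size=n_sites)
    for si in range(n_sites):
        pos = int(pos_arr[si])
        for j in range(counts[si]):
            length = int(simulate_fragments(scenario, 1, rng, loc=frag_loc)[0])
            start = int(rng.integers(max(1, pos - length + 1), pos + 1))
            end = min(start + length - 1, genome_len)
            seq = sequence[start - 1 : end].copy()
            # Substitute this individual's alleles at every covered panel site.
            lo = np.searchsorted(pos_arr, start, side="left")
            hi = np.searchsorted(pos_arr, end, side="right")
            for k in range(lo, hi):
                carries_ref = rng.random() < dosages[k] / 2.0
                seq[int(pos_arr[k]) - start] = freqs.ref[k] if carries_ref else freqs.alt[k]
            # Per-base sequencing error.
            errs = np.flatnonzero(rng.random(len(seq)) < err)
            for e_i in errs:
                others = bases.replace(str(seq[e_i]), "")
                seq[e_i] = others[int(rng.integers(3))]
            # Generation-side mapping bias: alt-carrying reads at the focal
            # site are dropped with probability beta.
            if scenario.beta > 0 and seq[pos - start] == freqs.alt[si]:
                if rng.random() < scenario.beta:
                    continue
            reads.append(
                AlignedRead(
                    name=f"{individual}:{si}:{j}",
                    chrom=scenario.chrom,
                    start=start,
                    seq="".join(seq),
                    quals=(scenario.error_q,) * len(seq),
                    mapq=scenario.mapq,
                )
            )
    return reads


class BiasedMapper:
    """Parametric reference-biased mapper adapter.

    Retains every reference-carrying read; drops each alternative-carrying
    read independently with probability ``beta``.  ``beta = 0`` is the
    identity mapper.  Allele identity is judged at the read's tagged flip
    site using the panel's ref/alt alleles.
    """

    def __init__(
        self,
        beta: float,
        panel: SnpPanel,
        rng: Union[int, np.random.Generator] = 0,
        mapq: int = 60,
    ):
        if not 0.0 <= beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        self.beta = beta
        self.lookup = panel.by_key()
        self.rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.mapq = mapq

    def map(self, reads: Sequence[FlippedRead]) -> list[Optional[AlignedRead]]:
        out: list[Optional[AlignedRead]] = []
        for fr in reads:
            site = self.lookup.get((fr.origin_chrom, fr.origin_pos))
            base = fr.base_at_site()
            dropped = (
                self.beta > 0
                and site is not None
                and base == site.alt_allele
                and self.rng.random() < self.beta
            )
            if dropped:
                out.append(None)
            else:
                out.append(replace(fr.source, name=fr.name, mapq=self.mapq))
        return out


def biased_mapper(
    beta: float,
    panel: SnpPanel,
    seed: Union[int, np.random.Generator] = 0,
    mapq: int = 60,
) -> BiasedMapper:
    """Convenience constructor mirroring :class:`BiasedMapper`."""
    return BiasedMapper(beta, panel, seed, mapq)


@dataclass
class SimBundle:
    """A self-consistent simulated dataset plus its ground truth."""

    scenario: SimScenario
    panel: SnpPanel
    truth: SimTruth
    sequence: np.ndarray
    reads: dict[str, list[AlignedRead]] = field(default_factory=dict)  # individual -> reads

    def individuals(self, pop: str) -> list[str]:
        return [f"{pop}_{i}" for i in range(self.scenario.n_ind)]

    def observations(
        self, individual: str, min_mapq: int = 30, min_baseq: int = 30
    ) -> dict[tuple[str, int], list[ReadObservation]]:
        return collect_observations(
            self.reads[individual], self.panel, min_mapq=min_mapq, min_baseq=min_baseq
        )


def generate_scenario_bundle(
    scenario: SimScenario,
    outdir: Optional[Union[str, Path]] = None,
    read_pops: Sequence[str] = ("T",),
) -> SimBundle:
    """Generate a complete reproducible bundle from one scenario.

    Frequencies, ascertainment, genotypes and reads all derive from child
    streams of ``scenario.seed``, so the same scenario yields byte-identical
    outputs.  Reads are generated only for ``read_pops`` (sources usually
    enter downstream analyses through their true frequencies).  When
    ``outdir`` is given, the panel, truth tables and per-individual pileup
    observations are written there as TSV.
    """
    root = np.random.SeedSequence(scenario.seed)
    s_freq, s_asc, s_geno, s_reads = root.spawn(4)
    freqs_raw = simulate_frequencies(scenario, np.random.default_rng(s_freq))
    keep = ascertain_sites(freqs_raw, scenario, np.random.default_rng(s_asc))
    freqs = freqs_raw.subset(keep)
    genotypes = simulate_genotypes(freqs, scenario, np.random.default_rng(s_geno))
    panel = freqs.to_panel(scenario.chrom)

    sequence = _materialize_reference(freqs, scenario)
    admixture = {
        f"{pop}_{i}": (scenario.f if pop == "T" else 0.0)
        for pop in POPULATIONS
        for i in range(scenario.n_ind)
    }
    truth = SimTruth(freqs=freqs, genotypes=genotypes, admixture=admixture)
    bundle = SimBundle(scenario=scenario, panel=panel, truth=truth, sequence=sequence)

    read_streams = s_reads.spawn(len(read_pops) * scenario.n_ind)
    k = 0
    for pop in read_pops:
        for i in range(scenario.n_ind):
            name = f"{pop}_{i}"
            bundle.reads[name] = simulate_reads(
                genotypes[pop][i], freqs, scenario,
                np.random.default_rng(read_streams[k]), sequence, individual=name,
            )
            k += 1

    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _materialize_reference(freqs: SiteFrequencies, scenario: SimScenario) -> np.ndarray:
    """Reference sequence consistent with the panel's ref alleles.

    Regenerated i.i.d. at the scenario's GC content from a fixed child seed
    and overwritten with the panel reference alleles at panel positions, so
    reads carrying the reference allele match the mapping reference exactly.
    """
    length = int(freqs.positions[-1]) + scenario.site_spacing if len(freqs) else scenario.site_spacing
    seq = simulate_ancestral_sequence(
        length, scenario.gc, np.random.default_rng(scenario.seed + 1_000_003)
    )
    seq[freqs.positions - 1] = freqs.ref
    return seq


def _write_bundle(bundle: SimBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_panel(bundle.panel, outdir / "panel.tsv")
    freqs = bundle.truth.freqs
    with (outdir / "truth_freqs.tsv").open("w") as fh:
        fh.write("#CHROM\tPOS\tREF\tALT\t" + "\t".join(POPULATIONS) + "\n")
        for i in range(len(freqs)):
            row = [bundle.scenario.chrom, str(int(freqs.positions[i])),
                   str(freqs.ref[i]), str(freqs.alt[i])]
            row += [f"{freqs.freqs[pop][i]:.6f}" for pop in POPULATIONS]
            fh.write("\t".join(row) + "\n")
    with (outdir / "truth_genotypes.tsv").open("w") as fh:
        inds = [f"{pop}_{i}" for pop in POPULATIONS for i in range(bundle.scenario.n_ind)]
        fh.write("#CHROM\tPOS\t" + "\t".join(inds) + "\n")
        for si in range(len(freqs)):
            row = [bundle.scenario.chrom, str(int(freqs.positions[si]))]
            for pop in POPULATIONS:
                row += [str(int(g)) for g in bundle.truth.genotypes[pop][:, si]]
            fh.write("\t".join(row) + "\n")
    with (outdir / "truth_admixture.tsv").open("w") as fh:
        fh.write("#IND\tF\n")
        for ind, f_true in sorted(bundle.truth.admixture.items()):
            fh.write(f"{ind}\t{f_true:.6f}\n")
    with (outdir / "observations.tsv").open("w") as fh:
        fh.write("#IND\tCHROM\tPOS\tBASE\tBASEQ\tMAPQ\tREAD_ID\n")
        for ind in sorted(bundle.reads):
            obs_by_site = bundle.observations(ind, min_mapq=0, min_baseq=0)
            for site in bundle.panel:
                for o in obs_by_site[site.key]:
                    fh.write(
                        f"{ind}\t{site.chrom}\t{site.pos}\t{o.base}\t"
                        f"{o.base_quality}\t{o.mapping_quality}\t{o.read_id}\n"
                    )
    with (outdir / "scenario.cfg").open("w") as fh:
        for key, val in vars(bundle.scenario).items():
            fh.write(f"{key} = {val}\n")


def write_bam(
    reads: Sequence[AlignedRead],
    chrom: str,
    chrom_length: int,
    path: Union[str, Path],
) -> Path:
    """Export simulated reads as a coordinate-sorted, indexed BAM."""
    import pysam

    path = Path(path)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": int(chrom_length)}]}
    ordered = sorted(reads, key=lambda r: (r.chrom, r.start, r.name))
    with pysam.AlignmentFile(str(path), "wb", header=header) as fh:
        for r in ordered:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = r.name
            seg.query_sequence = r.seq
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(min(q, 93) + 33) for q in r.quals)
            )
            seg.reference_id = 0
            seg.reference_start = r.start - 1
            seg.mapping_quality = r.mapq
            seg.cigarstring = f"{len(r.seq)}M"
            seg.flag = 16 if r.is_reverse else 0
            fh.write(seg)
    pysam.index(str(path))
    return path
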