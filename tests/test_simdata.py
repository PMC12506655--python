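import numpy as np
import pytest

from biasgl.reads import FlippedRead
from biasgl.simdata import (
    BiasedMapper,
    SimScenario,
    ascertain_sites,
    generate_scenario_bundle,
    simulate_ancestral_sequence,
    simulate_fragments,
    simulate_frequencies,
    simulate_genotypes,
)
from biasgl.simdata import _bn_drift


class TestAncestralSequence:
    def test_gc_content_within_3se(self):
        n = 200_000
        seq = simulate_ancestral_sequence(n, gc=0.41, rng=1)
        gc = np.isin(seq, ["G", "C"]).mean()
        se = np.sqrt(0.41 * 0.59 / n)
        assert abs(gc - 0.41) < 3 * se

    def test_g_and_c_equally_likely(self):
        n = 200_000
        seq = simulate_ancestral_sequence(n, gc=0.41, rng=2)
        pg = (seq == "G").mean()
        se = np.sqrt(0.205 * 0.795 / n)
        assert abs(pg - 0.205) < 3 * se

    def test_gc_zero_is_at_only(self):
        seq = simulate_ancestral_sequence(5000, gc=0.0, rng=3)
        assert set(seq) <= {"A", "T"}

    def test_length_validated(self):
        with pytest.raises(ValueError):
            simulate_ancestral_sequence(0)


class TestFrequencies:
    def test_pulse_extremes_are_exact(self):
        for f, source in ((0.0, "S2"), (1.0, "S3")):
            sc = SimScenario(n_sites=50, f=f, seed=4)
            fr = simulate_frequencies(sc, np.random.default_rng(0))
            np.testing.assert_array_equal(fr.freqs["T"], fr.freqs[source])

    def test_intermediate_pulse_is_linear_mixture(self):
        sc = SimScenario(n_sites=50, f=0.3, seed=4)
        fr = simulate_frequencies(sc, np.random.default_rng(0))
        np.testing.assert_allclose(
            fr.freqs["T"], 0.3 * fr.freqs["S3"] + 0.7 * fr.freqs["S2"], rtol=1e-12
        )

    def test_zero_drift_time_freezes_frequencies(self):
        sc = SimScenario(n_sites=200, t123=0.0, seed=5)
        fr = simulate_frequencies(sc, np.random.default_rng(1))
        np.testing.assert_array_equal(fr.freqs["S1"], fr.freqs["S2"])
        np.testing.assert_array_equal(fr.freqs["S1"], fr.freqs["S3"])

    def test_drift_f_formula(self):
        sc = SimScenario(ne=10_000)
        assert sc.drift_f(0.0) == 0.0
        assert sc.drift_f(20_000.0) == pytest.approx(1 - np.exp(-1.0))
        assert sc.t23 == pytest.approx(0.5 * sc.t123)
        assert sc.t_t_s2 == pytest.approx(0.2 * sc.t123)

    def test_bn_drift_moments(self):
        """Balding-Nichols: E[p'] = p and Var[p'] = F p (1-p)."""
        rng = np.random.default_rng(6)
        for F in (0.01, 0.1):
            p = np.full(200_000, 0.3)
            child = _bn_drift(rng, p, F)
            assert child.mean() == pytest.approx(0.3, abs=3 * np.sqrt(F * 0.21 / len(p)))
            assert child.var() == pytest.approx(F * 0.21, rel=0.1)

    def test_panel_is_transversions_only(self):
        sc = SimScenario(n_sites=150, seed=7)
        fr = simulate_frequencies(sc, np.random.default_rng(2))
        panel = fr.to_panel(sc.chrom)
        assert all(s.is_transversion for s in panel)

    def test_reference_pop_makes_reference_major(self):
        """A population-sampled reference haplotype makes reference alleles
        predominantly the major allele in that population."""
        anc = simulate_frequencies(SimScenario(n_sites=500, seed=8),
                                   np.random.default_rng(3))
        pop = simulate_frequencies(SimScenario(n_sites=500, seed=8, reference_pop="S2"),
                                   np.random.default_rng(3))
        assert anc.freqs["S2"].mean() == pytest.approx(0.5, abs=0.05)
        assert pop.freqs["S2"].mean() > 0.6

    def test_unknown_reference_pop_rejected(self):
        with pytest.raises(ValueError, match="reference_pop"):
            simulate_frequencies(SimScenario(n_sites=20, reference_pop="X"),
                                 np.random.default_rng(0))


class TestAscertainment:
    def test_keeps_requested_count_and_sorted(self):
        sc = SimScenario(n_sites=100, seed=9)
        fr = simulate_frequencies(sc, np.random.default_rng(4))
        idx = ascertain_sites(fr, sc, np.random.default_rng(5))
        assert len(idx) == 100
        assert np.all(np.diff(idx) > 0)

    def test_common_variant_enrichment(self):
        """Surviving sites are enriched for common variants relative to the
        raw candidates."""
        sc = SimScenario(n_sites=300, seed=10)
        fr = simulate_frequencies(sc, np.random.default_rng(6))
        idx = ascertain_sites(fr, sc, np.random.default_rng(7))
        maf = np.minimum(fr.freqs["S1"], 1 - fr.freqs["S1"])
        assert maf[idx].mean() > maf.mean()

    def test_impossible_threshold_raises(self):
        sc = SimScenario(n_sites=30, seed=11)
        fr = simulate_frequencies(sc, np.random.default_rng(8))
        with pytest.raises(ValueError, match="ascertainment"):
            ascertain_sites(fr, sc, np.random.default_rng(9), maf_min=0.6)


def test_genotypes_match_frequencies():
    sc = SimScenario(n_sites=400, n_ind=200, seed=12)
    fr = simulate_frequencies(sc, np.random.default_rng(10), n_sites=400)
    geno = simulate_genotypes(fr, sc, np.random.default_rng(11))
    assert geno["T"].shape == (200, 400)
    assert set(np.unique(geno["T"])) <= {0, 1, 2}
    # sample frequency tracks the true frequency across sites
    emp = geno["S2"].mean(axis=0) / 2
    resid = emp - fr.freqs["S2"]
    assert np.abs(resid.mean()) < 0.01
    assert np.corrcoef(emp, fr.freqs["S2"])[0, 1] > 0.95


class TestFragments:
    def test_minimum_length_enforced(self):
        sc = SimScenario(frag_min=30)
        lens = simulate_fragments(sc, 3000, np.random.default_rng(12), loc=3.3)
        assert lens.min() >= 30

    def test_mean_scales_with_location(self):
        sc = SimScenario()
        short = simulate_fragments(sc, 5000, np.random.default_rng(13), loc=3.3).mean()
        long = simulate_fragments(sc, 5000, np.random.default_rng(14), loc=3.8).mean()
        assert 30 <= short < long <= 60


class TestReads:
    def test_site_coverage_matches_depth(self):
        sc = SimScenario(n_sites=300, n_ind=1, depth=0.5, seed=15)
        b = generate_scenario_bundle(sc)
        cov = [len(v) for v in b.observations("T_0", min_baseq=0, min_mapq=0).values()]
        mean = np.mean(cov + [0] * (len(b.panel) - len(cov)))
        se = np.sqrt(0.5 / len(b.panel))
        assert abs(mean - 0.5) < 4 * se

    def test_error_free_reads_carry_panel_alleles(self):
        sc = SimScenario(n_sites=100, n_ind=1, depth=2.0, seed=16, error_q=93)
        b = generate_scenario_bundle(sc)
        lookup = b.panel.by_key()
        for key, obs_list in b.observations("T_0").items():
            site = lookup[key]
            for o in obs_list:
                assert o.base in (site.ref_allele, site.alt_allele)

    def test_generation_side_beta_drops_alt_reads(self):
        """At beta = 1 with hom-alt truth no focal-site reads survive."""
        from biasgl.simdata import simulate_reads

        sc = SimScenario(n_sites=80, n_ind=1, depth=3.0, seed=17, beta=1.0, error_q=93)
        fr = simulate_frequencies(sc, np.random.default_rng(20), n_sites=80)
        dos = np.zeros(80, dtype=int)  # hom-alt at every site (ref dosage 0)
        seq = simulate_ancestral_sequence(int(fr.positions[-1]) + 400, sc.gc, 21)
        reads = simulate_reads(dos, fr, sc, np.random.default_rng(22), seq)
        for r in reads:  # survivors never carry the alternative at their focal site
            si = int(r.name.split(":")[1])
            assert r.base_at(int(fr.positions[si])) != str(fr.alt[si])
        # with hom-alt truth and beta = 1 almost no focal reads survive
        assert len(reads) < 80 * 3.0 * 0.05


class TestBiasedMapper:
    def _flips(self, panel, bases, n):
        from biasgl.reads import AlignedRead

        site = panel[0]
        out = []
        for i in range(n):
            src = AlignedRead(
                name=f"r{i}", chrom=site.chrom, start=site.pos - 2,
                seq="GG" + bases[i % len(bases)] + "GG", quals=(40,) * 5, mapq=60,
            )
            out.append(FlippedRead(source=src, origin_chrom=site.chrom,
                                   origin_pos=site.pos, flipped_to=bases[i % len(bases)]))
        return out

    def test_beta_zero_retains_everything(self, panel3):
        flips = self._flips(panel3, [panel3[0].ref_allele, panel3[0].alt_allele], 40)
        assert all(a is not None for a in BiasedMapper(0.0, panel3, 0).map(flips))

    def test_beta_one_drops_every_alt(self, panel3):
        flips = self._flips(panel3, [panel3[0].alt_allele], 40)
        assert all(a is None for a in BiasedMapper(1.0, panel3, 0).map(flips))
        flips = self._flips(panel3, [panel3[0].ref_allele], 40)
        assert all(a is not None for a in BiasedMapper(1.0, panel3, 0).map(flips))

    def test_intermediate_beta_drop_rate(self, panel3):
        n = 4000
        flips = self._flips(panel3, [panel3[0].alt_allele], n)
        mapped = BiasedMapper(0.2, panel3, 1).map(flips)
        drop = sum(a is None for a in mapped) / n
        assert abs(drop - 0.2) < 3 * np.sqrt(0.2 * 0.8 / n)

    def test_invalid_beta(self, panel3):
        with pytest.raises(ValueError):
            BiasedMapper(1.5, panel3, 0)


class TestBundle:
    def test_same_seed_reproduces_exactly(self):
        sc = SimScenario(n_sites=60, n_ind=2, depth=1.0, seed=30)
        a = generate_scenario_bundle(sc)
        b = generate_scenario_bundle(sc)
        np.testing.assert_array_equal(a.truth.freqs.freqs["T"], b.truth.freqs.freqs["T"])
        assert [(r.name, r.start, r.seq) for r in a.reads["T_0"]] == [
            (r.name, r.start, r.seq) for r in b.reads["T_0"]
        ]

    def test_different_seed_differs(self):
        a = generate_scenario_bundle(SimScenario(n_sites=60, n_ind=1, depth=1.0, seed=30))
        b = generate_scenario_bundle(SimScenario(n_sites=60, n_ind=1, depth=1.0, seed=31))
        assert not np.array_equal(a.truth.freqs.freqs["T"], b.truth.freqs.freqs["T"])

    def test_truth_admixture_records_pulse_fraction(self):
        b = generate_scenario_bundle(SimScenario(n_sites=20, n_ind=3, depth=0.5,
                                                 f=0.35, seed=32))
        assert all(v == pytest.approx(0.35) for k, v in b.truth.admixture.items()
                   if k.startswith("T_"))

    def test_written_bundle_is_byte_identical(self, tmp_path):
        sc = SimScenario(n_sites=40, n_ind=2, depth=1.0, seed=33)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_scenario_bundle(sc, outdir=d1)
        generate_scenario_bundle(sc, outdir=d2)
        files = sorted(p.name for p in d1.iterdir())
        assert "panel.tsv" in files and "observations.tsv" in files
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name
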