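"""Generator contracts: structure, determinism, planted-site invariants and
the statistical behaviour of the fragment and qPCR simulators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import meriptools as mt
from meriptools.simulate import (
    MotifDeficitError,
    RRACH_FWD,
    SimulationSizingError,
    simulate_qpcr,
    substream,
    titration_design,
)


class TestAnnotation:
    def test_gene_models_have_full_structure(self, tiny_study):
        ann = tiny_study.annotation
        coding = [t for t in ann.transcripts.values() if t.biotype == "protein_coding"]
        assert len(coding) == tiny_study.cfg.n_genes
        for tx in coding:
            assert tx.utr5_len > 0 and tx.cds_len > 0 and tx.utr3_len > 0
            assert tx.cds_len % 3 == 0
            assert tx.exonic_length == tx.utr5_len + tx.cds_len + tx.utr3_len
            # annotated stop codon is the CDS 3' terminus
            lo, hi = tx.stop_codon_tx_interval
            assert hi == tx.utr5_len + tx.cds_len and hi - lo == 3
        assert {t.strand for t in coding} == {"+", "-"}

    def test_retro_loci_counts_and_labels(self, tiny_study):
        loci = tiny_study.annotation.retro_loci
        mta = [l for l in loci if l.subfamily == "MTA"]
        assert len(mta) == 5
        assert all(l.consensus_length == 500 and l.length == 500 for l in mta)

    def test_spikeins_are_single_exon_contig_transcripts(self, tiny_study):
        ann = tiny_study.annotation
        for name in ann.spikein_contigs:
            tx = ann.transcripts[name]
            assert tx.exons == ((0, ann.chrom_lengths[name]),)
            assert not tx.is_coding

    def test_same_seed_reproduces_annotation_and_sequence(self, tiny_cfg):
        a1, g1 = mt.generate_annotation(tiny_cfg)
        a2, g2 = mt.generate_annotation(tiny_cfg)
        assert g1 == g2
        assert a1.transcripts == a2.transcripts
        assert a1.retro_loci == a2.retro_loci

    def test_oversized_request_raises_sizing_error(self):
        with pytest.raises(SimulationSizingError):
            mt.generate_annotation(
                mt.SimConfig(n_genes=500, n_chroms=1, chrom_length_bp=50_000)
            )

    def test_exons_contain_injected_rrach(self, tiny_study):
        ann, genome = tiny_study.annotation, tiny_study.genome
        n = sum(
            len(RRACH_FWD.findall(tx.spliced_sequence(genome)))
            for tx in ann.transcripts.values()
            if tx.biotype == "protein_coding"
        )
        assert n >= tiny_study.cfg.n_m6a_sites


class TestPlanting:
    def test_every_site_sits_on_rrach_a(self, study):
        assert mt.verify_sites_on_rrach(study.truth, study.annotation, study.genome)

    def test_stop_bias_one_puts_all_sites_near_stop(self, tiny_study):
        cfg = mt.SimConfig(**{**tiny_study.cfg.__dict__, "stop_codon_bias": 1.0})
        truth = mt.plant_m6a_sites(tiny_study.annotation, tiny_study.genome, cfg)
        for s in truth.sites:
            tx = tiny_study.annotation.transcripts[s.transcript_id]
            lo, hi = tx.stop_codon_tx_interval
            dist = max(lo - s.tx_position, s.tx_position - (hi - 1), 0)
            assert dist <= 400

    def test_stop_proximal_count_in_binomial_band(self, study):
        # n=200, p=0.7: the 95% binomial band is contained in [120, 160]
        n_prox = 0
        for s in study.truth.sites:
            tx = study.annotation.transcripts[s.transcript_id]
            lo, hi = tx.stop_codon_tx_interval
            if max(lo - s.tx_position, s.tx_position - (hi - 1), 0) <= 400:
                n_prox += 1
        assert 120 <= n_prox <= 160

    def test_zero_sites_gives_empty_registry_and_no_true_peaks(self, tiny_study):
        cfg = mt.SimConfig(**{**tiny_study.cfg.__dict__, "n_m6a_sites": 0})
        truth = mt.plant_m6a_sites(tiny_study.annotation, tiny_study.genome, cfg)
        assert truth.sites == []

    def test_motif_deficit_is_reported_with_counts(self, tiny_study):
        cfg = mt.SimConfig(**{**tiny_study.cfg.__dict__, "n_m6a_sites": 100_000})
        with pytest.raises(MotifDeficitError, match="candidates"):
            mt.plant_m6a_sites(tiny_study.annotation, tiny_study.genome, cfg)

    def test_stoichiometry_within_configured_range(self, study):
        lo, hi = study.cfg.stoichiometry_range
        st = [s.stoichiometry for s in study.truth.sites]
        assert min(st) >= lo and max(st) <= hi


class TestFragments:
    def test_same_seed_gives_identical_fragments(self, tiny_study):
        cfg = tiny_study.cfg
        args = (tiny_study.annotation, tiny_study.truth, tiny_study.expression, cfg)
        f1 = mt.simulate_fragments(*args, "IP", stream_extra=(9,))
        f2 = mt.simulate_fragments(*args, "IP", stream_extra=(9,))
        assert f1.fragments == f2.fragments

    def test_fragments_respect_bounds_and_min_length(self, tiny_study):
        frags = tiny_study.get("cond0", 1, "input")
        frags.validate_bounds(tiny_study.annotation.chrom_lengths)
        assert all(
            sum(e - s for s, e in f.blocks) >= tiny_study.cfg.min_fragment_length
            for f in frags.fragments
        )

    def test_zero_depth_is_a_valid_empty_library(self, tiny_study):
        out = mt.simulate_fragments(
            tiny_study.annotation, tiny_study.truth, tiny_study.expression,
            tiny_study.cfg, "input", n_fragments=0,
        )
        assert len(out) == 0

    def test_pure_signal_ip_only_emits_site_covering_fragments(self, tiny_study):
        cfg = mt.SimConfig(
            **{
                **tiny_study.cfg.__dict__,
                "background_binding_rate": 0.0,
                "stoichiometry_range": (1.0, 1.0),
                "n_fragments_per_sample": 2_000,
            }
        )
        truth = mt.plant_m6a_sites(tiny_study.annotation, tiny_study.genome, cfg)
        ip = mt.simulate_fragments(
            tiny_study.annotation, truth, tiny_study.expression, cfg, "IP"
        )
        positions = {}
        for s in truth.all_sites:
            positions.setdefault(s.chrom, []).append(s.position)
        for f in ip.fragments:
            assert any(
                bs <= p < be
                for p in positions.get(f.chrom, [])
                for bs, be in f.blocks
            )

    def test_input_counts_match_expression_length_weights(self, tiny_study):
        """Chi-square goodness of fit of per-unit fragment counts against
        expression x length multinomial weights at n = 1e5."""
        ann, truth, expr = (
            tiny_study.annotation, tiny_study.truth, tiny_study.expression,
        )
        inp = mt.simulate_fragments(
            tiny_study.annotation, truth, expr, tiny_study.cfg, "input",
            n_fragments=100_000, stream_extra=(77,),
        )
        units = {
            tx.transcript_id: expr[tx.transcript_id] * tx.exonic_length
            for tx in ann.transcripts.values()
        }
        for loc in ann.retro_loci:
            units[loc.locus_id] = expr[loc.locus_id] * loc.length
        weights = pd.Series(units)
        probs = weights / weights.sum()
        # count fragments per unit via midpoint containment in the source unit
        observed = pd.Series(0.0, index=probs.index)
        spans = []
        for tid, tx in ann.transcripts.items():
            spans.append((tx.chrom, *tx.span, tid))
        for loc in ann.retro_loci:
            spans.append((loc.chrom, loc.start, loc.end, loc.locus_id))
        for f in inp.fragments:
            mid = (f.start + f.end) // 2
            for chrom, s, e, uid in spans:
                if chrom == f.chrom and s <= mid < e:
                    observed[uid] += 1
                    break
        expected = probs * observed.sum()
        # pool units with small expectation for chi-square validity
        big = expected >= 5
        obs = observed[big].to_numpy()
        exp = expected[big].to_numpy()
        if (~big).any():
            obs = np.append(obs, observed[~big].sum())
            exp = np.append(exp, expected[~big].sum())
        _, p = stats.chisquare(obs, exp)
        assert p > 0.001

    def test_ip_enrichment_at_sites_exceeds_background_positions(self, study):
        """Paired comparison over >=50 sites: IP/input bin-count ratio at the
        planted A beats the ratio 500 bp away on the same transcript."""
        ann = study.annotation
        bw = 10
        ip_t = mt.bin_coverage(study.get("cond0", 1, "IP"), ann.chrom_lengths, bw,
                               normalize="counts")
        in_t = mt.bin_coverage(study.get("cond0", 1, "input"), ann.chrom_lengths, bw,
                               normalize="counts")
        site_pos = {(s.chrom, s.position) for s in study.truth.all_sites}
        diffs = []
        for s in study.truth.sites:
            tx = ann.transcripts[s.transcript_id]
            alt_tx = (s.tx_position + 500) % tx.exonic_length
            alt = tx.tx_to_genome(alt_tx)
            if any((s.chrom, p) in site_pos
                   for p in range(alt - 300, alt + 301)):
                continue
            def ratio(chrom, pos):
                b = pos // bw
                return (ip_t.values[chrom][b] + 1) / (in_t.values[chrom][b] + 1)
            diffs.append(ratio(s.chrom, s.position) - ratio(s.chrom, alt))
            if len(diffs) >= 80:
                break
        assert len(diffs) >= 50
        assert np.median(diffs) > 0
        assert np.mean(np.array(diffs) > 0) >= 0.9


class TestStudy:
    def test_conditions_get_disjoint_site_sets(self, two_condition_study):
        sets = [
            {(s.chrom, s.position) for s in t.sites}
            for t in two_condition_study.truths
        ]
        assert sets[0] and sets[1] and not (sets[0] & sets[1])

    def test_sample_sheet_covers_all_libraries(self, tiny_study):
        sheet = tiny_study.sample_sheet()
        assert len(sheet) == tiny_study.cfg.replicates * 2
        assert set(sheet["role"]) == {"IP", "input"}


class TestQpcrSimulation:
    def test_twofold_concentration_is_minus_one_delta_ct(self):
        cfg = mt.SimConfig()
        design = pd.DataFrame(
            {"sample": ["a", "b"], "target": "t", "assay": "IP",
             "concentration": [2.0, 1.0]}
        )
        tab = simulate_qpcr(design, cfg)
        assert tab["Ct"][0] - tab["Ct"][1] == pytest.approx(-1.0)

    def test_zero_concentration_is_censored(self):
        tab = simulate_qpcr(
            pd.DataFrame({"sample": ["a"], "target": "t", "assay": "IP",
                          "concentration": [0.0]}),
            mt.SimConfig(),
        )
        assert np.isnan(tab["Ct"][0])

    def test_noiseless_titration_recovers_exact_levels(self):
        tab = simulate_qpcr(titration_design(), mt.SimConfig())
        recs = [
            mt.QpcrRecord(r.sample, r.target, "IP", float(r.Ct))
            for r in tab.itertuples()
        ]
        res = mt.titration_levels(
            recs, dict(zip(tab["sample"], tab["expected_level"])), "mix100"
        )
        assert res.table["observed"].tolist() == pytest.approx(
            [100.0, 80.0, 50.0, 20.0, 0.0]
        )

    def test_noisy_titration_median_r_at_least_099(self):
        """Monte-Carlo: Ct noise sd 0.1 over 100 seeds."""
        rs = []
        for seed in range(100):
            cfg = mt.SimConfig(seed=seed, qpcr_ct_sd=0.1)
            tab = simulate_qpcr(titration_design(), cfg)
            recs = [
                mt.QpcrRecord(r.sample, r.target, "IP", float(r.Ct))
                for r in tab.itertuples()
            ]
            res = mt.titration_levels(
                recs, dict(zip(tab["sample"], tab["expected_level"])), "mix100"
            )
            rs.append(res.pearson_r)
        assert np.median(rs) >= 0.99


def test_substreams_are_independent_per_stage():
    a = substream(1, "annotation").integers(0, 1_000_000, 5)
    b = substream(1, "sites").integers(0, 1_000_000, 5)
    assert not np.array_equal(a, b)
    assert np.array_equal(a, substream(1, "annotation").integers(0, 1_000_000, 5))
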