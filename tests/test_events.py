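"""Event calling, the filter cascade and event classification."""

import numpy as np
import pandas as pd
import pytest

from meiorec.events import (
    CrossoverCall,
    FilterConfig,
    NcoCall,
    apply_filters,
    assign_parent_of_origin,
    assign_recipient_homologue,
    call_crossovers,
    call_nco_candidates,
    classify_inheritance,
    de_novo_fraction,
    dissolve_short_segments,
    estimate_validated_fraction,
    overlap_hotspots,
)
from meiorec.hmm import BackgroundSegment
from meiorec.pipeline import call_cohort, truth_recovery
from meiorec.simulate import SampleGenotypes


def seg(state, start, end, pos_per_snp=100, sample="s", chrom="chr1"):
    return BackgroundSegment(
        sample, chrom, start, end, state, 1.0,
        (start + 1) * pos_per_snp, (end + 1) * pos_per_snp,
    )


class _Map:
    def __init__(self, positions, chrom="chr1"):
        self.chroms = [chrom]
        self.pos = {chrom: np.asarray(positions, dtype=np.int64)}
        self.chrom_lengths = {chrom: int(positions[-1]) + 1000}

    def n_sites(self, chrom):
        return len(self.pos[chrom])


def _geno(calls, depth=20, sample="s", gen="F2", chrom="chr1"):
    calls = np.asarray(calls, dtype=np.int8)
    n = len(calls)
    d = np.full(n, depth, dtype=np.int32)
    adb = np.where(calls == 0, d, np.where(calls == 1, d // 2, 0)).astype(np.int32)
    adb[calls == -1] = 0
    g = SampleGenotypes(sample, gen, {chrom: calls}, {chrom: d},
                        {chrom: adb}, {chrom: d - adb})
    g.depth[chrom][calls == -1] = 0
    g.ad_cast[chrom][calls == -1] = 0
    return g


class TestCrossoverCalls:
    def test_state_change_emits_one_call(self):
        segs = [seg("BB", 0, 9), seg("BC", 10, 19)]
        calls = call_crossovers(segs)
        assert len(calls) == 1
        co = calls[0]
        assert (co.left_snp_pos, co.right_snp_pos) == (1000, 1100)
        assert co.resolution == 100
        assert not co.complex

    def test_no_state_change_no_calls(self):
        assert call_crossovers([seg("BC", 0, 50)]) == []

    def test_direct_bb_cc_switch_flagged_complex(self):
        calls = call_crossovers([seg("BB", 0, 9), seg("CC", 10, 19)])
        assert len(calls) == 1 and calls[0].complex

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            CrossoverCall("s", "chr1", 500, 500, "BB", "BC")

    def test_double_switch_dissolved_to_candidates(self):
        # BB -> BC (2 SNPs) -> BB: an NCO-scale signal, not two COs
        segs = [seg("BB", 0, 9), seg("BC", 10, 11), seg("BB", 12, 29)]
        clean = dissolve_short_segments(segs, max_snps=10)
        assert len(clean) == 1 and clean[0].state == "BB"
        assert call_crossovers(clean) == []
        calls = np.zeros(30, dtype=np.int8)
        calls[10:12] = 1
        cands = call_nco_candidates(
            _geno(calls), clean, _Map(np.arange(30) * 100 + 100)
        )
        assert list(cands["snp_idx"]) == [10, 11]

    def test_short_segment_between_different_flanks_kept(self):
        segs = [seg("BB", 0, 9), seg("BC", 10, 11), seg("CC", 12, 29)]
        clean = dissolve_short_segments(segs, max_snps=10)
        assert len(clean) == 3


class TestNcoCandidates:
    @pytest.mark.parametrize(
        "bg,call,recipient,donor_cast",
        [
            ("CC", 1, "CAST", False),  # het in CC: CAST hap gained B6
            ("BB", 1, "B6", True),
            ("BC", 0, "CAST", False),  # homB6 in BC: CAST allele replaced
            ("BC", 2, "B6", True),
        ],
    )
    def test_conflict_definitions(self, bg, call, recipient, donor_cast):
        calls = np.full(21, {"BB": 0, "BC": 1, "CC": 2}[bg], dtype=np.int8)
        calls[10] = call
        cands = call_nco_candidates(
            _geno(calls), [seg(bg, 0, 20)], _Map(np.arange(21) * 170 + 1)
        )
        assert len(cands) == 1
        row = cands.iloc[0]
        assert row["recipient"] == recipient
        assert bool(row["donor_is_cast"]) == donor_cast

    def test_concordant_sample_gives_no_candidates(self):
        calls = np.ones(30, dtype=np.int8)
        cands = call_nco_candidates(
            _geno(calls), [seg("BC", 0, 29)], _Map(np.arange(30) * 170 + 1)
        )
        assert len(cands) == 0


def _founders(n, chrom="chr1"):
    return {
        "F0_B6": _geno(np.zeros(n), sample="F0_B6", gen="F0"),
        "F0_CAST": _geno(np.full(n, 2), sample="F0_CAST", gen="F0"),
    }


def _cand_row(**kw):
    base = dict(
        sample_id="s", chrom="chr1", snp_idx=5, pos=600, call=1,
        bg_state="BB", recipient="B6", donor_is_cast=True,
        depth=21, ad_b6=20, ad_cast=1,
    )
    base.update(kw)
    return base


class TestFilters:
    def test_unbalanced_het_removed(self):
        # AD (20, 1): two-sided binomial p << 0.01
        snp_map = _Map(np.arange(10) * 170 + 1)
        cands = pd.DataFrame([_cand_row(snp_idx=5, pos=snp_map.pos["chr1"][5])])
        ncos, report = apply_filters(cands, _founders(10), snp_map)
        assert report.removed["allele_balance"] == 1
        assert ncos == []
        assert report.check()

    def test_balanced_het_survives_and_merges(self):
        snp_map = _Map(np.arange(10) * 170 + 1)
        rows = [
            _cand_row(snp_idx=i, pos=snp_map.pos["chr1"][i],
                      depth=20, ad_b6=10, ad_cast=10)
            for i in (4, 5)
        ]
        ncos, report = apply_filters(pd.DataFrame(rows), _founders(10), snp_map)
        assert report.surviving == 2 and len(ncos) == 1
        assert ncos[0].n_converted == 2
        assert not ncos[0].complex

    def test_low_depth_hom_removed(self):
        snp_map = _Map(np.arange(10) * 170 + 1)
        cands = pd.DataFrame(
            [_cand_row(call=0, bg_state="BC", depth=3, ad_b6=3, ad_cast=0)]
        )
        _, report = apply_filters(cands, _founders(10), snp_map)
        assert report.removed["hom_depth"] == 1

    def test_excluded_region_counted(self):
        snp_map = _Map(np.arange(10) * 170 + 1)
        cands = pd.DataFrame(
            [_cand_row(pos=600, depth=20, ad_b6=10, ad_cast=10)]
        )
        fc = FilterConfig(exclusion_regions=[("chr1", 0, 1000)])
        _, report = apply_filters(cands, _founders(10), snp_map, fc)
        assert report.removed["excluded_region"] == 1

    def test_founder_het_site_removed(self):
        snp_map = _Map(np.arange(10) * 170 + 1)
        founders = _founders(10)
        founders["F0_B6"].calls["chr1"][5] = 1  # apparently het in F0
        cands = pd.DataFrame(
            [_cand_row(depth=20, ad_b6=10, ad_cast=10)]
        )
        _, report = apply_filters(cands, founders, snp_map)
        assert report.removed["founder"] == 1

    def test_gap_rule_splits_events(self):
        positions = np.array([100, 300, 5000, 5200])
        snp_map = _Map(positions)
        rows = [
            _cand_row(snp_idx=i, pos=positions[i], depth=20, ad_b6=10, ad_cast=10)
            for i in range(4)
        ]
        ncos, _ = apply_filters(pd.DataFrame(rows), _founders(4), snp_map)
        assert len(ncos) == 2

    def test_complex_flag_from_internal_unconverted(self):
        positions = np.array([100, 300, 500])
        snp_map = _Map(positions)
        rows = [
            _cand_row(snp_idx=i, pos=positions[i], depth=20, ad_b6=10, ad_cast=10)
            for i in (0, 2)  # middle SNP unconverted
        ]
        ncos, _ = apply_filters(pd.DataFrame(rows), _founders(3), snp_map)
        assert len(ncos) == 1 and ncos[0].complex
        assert ncos[0].min_tract == (100, 500)

    def test_max_tract_extends_to_flanking_snps(self):
        positions = np.array([100, 300, 500, 900])
        snp_map = _Map(positions)
        rows = [_cand_row(snp_idx=1, pos=300, depth=20, ad_b6=10, ad_cast=10),
                _cand_row(snp_idx=2, pos=500, depth=20, ad_b6=10, ad_cast=10)]
        ncos, _ = apply_filters(pd.DataFrame(rows), _founders(4), snp_map)
        assert ncos[0].min_tract == (300, 500)
        assert ncos[0].max_tract == (100, 900)

    def test_report_conservation_on_synthetic_run(self, small_cross):
        cfg, ped, geno = small_cross
        calls = call_cohort(geno, ped.snp_map, sample_ids=ped.samples("F2"))
        for c in calls.values():
            assert c.report.check()
            assert c.report.removed["allele_balance"] >= 0

    def test_noisy_run_removes_artifacts_with_high_precision(self, small_cross):
        cfg, ped, geno = small_cross
        calls = call_cohort(geno, ped.snp_map, sample_ids=ped.samples("F2"))
        total_removed = sum(
            sum(c.report.removed.values()) for c in calls.values()
        )
        assert total_removed > 0
        m = truth_recovery(ped, calls, interaction_bp=2000)
        assert m.nco_precision >= 0.9


class TestClassification:
    def test_de_novo_fraction_published_counts(self):
        assert de_novo_fraction(821, 1384) == pytest.approx(0.372, abs=5e-4)
        assert de_novo_fraction(510, 882) == pytest.approx(0.366, abs=5e-4)
        assert de_novo_fraction(0, 10) == 0.0

    def test_inherited_vs_de_novo_and_dedup(self):
        def nco(sample, positions):
            return NcoCall(
                sample, "chr1", np.array(positions), np.array(positions),
                np.array([1] * len(positions)), "BB", "B6",
                np.array([True] * len(positions)),
                (positions[0], positions[-1]), (0, 0),
            )

        child1 = nco("c1", [100, 200])
        child2 = nco("c2", [100, 200])  # sibling shares the event
        child3 = nco("c1", [900])
        parents_of = {"c1": ("m", "f"), "c2": ("m", "f")}
        parent_events = {"m": [nco("m", [100, 200])], "f": []}
        anns, distinct = classify_inheritance(
            [child1, child2, child3], parent_events, parents_of=parents_of
        )
        assert child1.inheritance == "inherited"
        assert child2.inheritance == "inherited"
        assert child3.inheritance == "de_novo"
        assert len(distinct) == 1  # sibling duplicates collapse

    def test_orphan_sample_unknown(self):
        ev = NcoCall(
            "orphan", "chr1", np.array([100]), np.array([0]),
            np.array([1]), "BB", "B6", np.array([True]), (100, 100), (0, 0),
        )
        anns, _ = classify_inheritance([ev], {}, parents_of={"orphan": (None, None)})
        assert ev.inheritance == "unknown"


class TestParentOfOrigin:
    def _nco(self, idx=(5,)):
        idx = np.array(idx)
        return NcoCall(
            "c", "chr1", idx * 170 + 1, idx, np.array([1] * len(idx)),
            "BB", "B6", np.array([True] * len(idx)),
            (int(idx[0]) * 170 + 1, int(idx[-1]) * 170 + 1), (0, 0),
            inheritance="de_novo",
        )

    def test_het_mother_hom_father_is_maternal(self):
        mother = _geno(np.ones(10))
        father = _geno(np.zeros(10))
        assert assign_parent_of_origin(self._nco(), mother, father) == "maternal"

    def test_both_parents_het_unknown(self):
        mother = _geno(np.ones(10))
        father = _geno(np.ones(10))
        assert assign_parent_of_origin(self._nco(), mother, father) == "unknown"

    def test_co_tracer_assigns_when_one_parent_fits(self):
        co = CrossoverCall("c", "chr1", 1000, 1100, "BB", "BC",
                           inheritance="de_novo")
        snp_map = _Map(np.arange(30) * 100 + 100)
        # mother is BC around the breakpoint (can supply B6 then CAST);
        # father is BB (static B6 only)
        m_segs = [seg("BC", 0, 29)]
        f_segs = [seg("BB", 0, 29)]
        lab = assign_parent_of_origin(
            co, None, None, m_segs, f_segs, snp_map
        )
        assert lab == "maternal"

    def test_co_tracer_ambiguous_unknown(self):
        co = CrossoverCall("c", "chr1", 1000, 1100, "BB", "BC",
                           inheritance="de_novo")
        snp_map = _Map(np.arange(30) * 100 + 100)
        m_segs = [seg("BC", 0, 29)]
        f_segs = [seg("BC", 0, 29)]
        assert (
            assign_parent_of_origin(co, None, None, m_segs, f_segs, snp_map)
            == "unknown"
        )

    def test_simulated_f5_assignments_match_truth(self):
        # small full pedigree; every confident assignment agrees with truth
        from meiorec.config import SimConfig
        from meiorec.pipeline import _truth_events_for
        from meiorec.simulate import simulate_genotype_calls, simulate_pedigree

        cfg = SimConfig(
            chrom_lengths=(3_000_000,), n_hotspots=300,
            dsb_per_meiosis_mean=100.0,
            exact_genotypes=True, base_error_rate=0.0,
            false_het_rate=0.0, false_hom_rate=0.0,
        )
        rng = np.random.default_rng(2)
        ped = simulate_pedigree(cfg, rng, n_lines=4, through="F5")
        geno = simulate_genotype_calls(ped, cfg, rng)
        calls = call_cohort(geno, ped.snp_map)
        f5 = [s for s in calls if s.startswith("F5")]
        n_ok = n_assigned = n_verifiable = 0
        for s in f5:
            ind = ped.individuals[s]
            truth = {"maternal": set(), "paternal": set()}
            for ev in _truth_events_for(ped, s):
                if ev.kind != "NCO" or ev.informative is None:
                    continue
                side = (
                    "maternal"
                    if ev.meiosis_id.split(">")[0] == ind.mother_id
                    else "paternal"
                )
                truth[side].update(
                    int(p) for p in ped.snp_map.pos[ev.chrom][ev.informative]
                )
            for e in calls[s].ncos:
                true_side = [
                    side
                    for side in ("maternal", "paternal")
                    if all(int(p) in truth[side] for p in e.positions)
                ]
                if len(true_side) != 1:
                    continue  # not verifiable from truth bookkeeping
                n_verifiable += 1
                lab = assign_parent_of_origin(
                    e, geno[ind.mother_id], geno[ind.father_id]
                )
                if lab != "unknown":
                    n_assigned += 1
                    n_ok += lab == true_side[0]
        assert 0 < n_assigned < n_verifiable  # fraction strictly in (0, 1)
        assert n_ok == n_assigned


class TestRecipientAndOverlap:
    def test_recipient_from_call(self):
        nco = NcoCall(
            "s", "chr1", np.array([100]), np.array([0]), np.array([1]),
            "CC", "CAST", np.array([False]), (100, 100), (0, 0),
        )
        assert assign_recipient_homologue(nco) == "CAST"

    def test_overlap_boundaries(self):
        peaks = pd.DataFrame(
            {"chrom": ["chr1"], "start": [10_000], "end": [11_000],
             "hotspot_id": [7]}
        )
        at_center = NcoCall(
            "s", "chr1", np.array([10_500]), np.array([0]), np.array([1]),
            "BB", "B6", np.array([True]), (10_500, 10_500), (0, 0),
        )
        far = NcoCall(
            "s", "chr1", np.array([12_001]), np.array([0]), np.array([1]),
            "BB", "B6", np.array([True]), (12_001, 12_001), (0, 0),
        )
        events, frac = overlap_hotspots([at_center, far], peaks, peaks.iloc[0:0])
        assert at_center.hotspot_id == 7
        assert far.hotspot_id is None
        assert frac == 0.5


class TestValidatedFraction:
    def test_published_arithmetic(self):
        v = estimate_validated_fraction(0.842, 1.0, 0.44)
        assert v == pytest.approx(0.9115, abs=2e-4)

    @pytest.mark.parametrize(
        "args,expected",
        [((1.0, 1.0, 0.0), 1.0), ((0.5, 0.8, 0.4), 0.6)],
    )
    def test_trivial_cases(self, args, expected):
        assert estimate_validated_fraction(*args) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            estimate_validated_fraction(1.2, 1.0, 0.5)
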