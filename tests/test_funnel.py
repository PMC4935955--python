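"""Funnel stage semantics, auditing, monotonicity and order-invariance."""

import numpy as np
import pytest

from exomescreen import fixtures, funnel, synthetic
from exomescreen.model import (
    HET,
    HOM_ALT,
    HOM_REF,
    CallSet,
    GenomicInterval,
    VariantRecord,
)


def _record(pos, ref="A", alt="C", chrom="9", mq=60.0, dp=50, qual=500.0,
            genotypes=None, annotations=None):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, mapping_quality=mq,
        read_depth=dp, call_quality=qual,
        genotypes=genotypes or {}, annotations=annotations or {},
    )


def _affected_pair(records1, records2):
    cs1 = CallSet(sample_id="A1", role="affected")
    cs2 = CallSet(sample_id="A2", role="affected")
    for rec in records1:
        rec.genotypes.setdefault("A1", HOM_ALT)
        cs1.add(rec)
    for rec in records2:
        rec.genotypes.setdefault("A2", HOM_ALT)
        cs2.add(rec)
    return cs1, cs2


class TestStageConstruction:
    def _panels(self):
        return [CallSet(sample_id="db", role="known_db")], CallSet(
            sample_id="es", role="es_line"
        )

    def test_default_standard_stages(self):
        panels, es = self._panels()
        config = funnel.FunnelConfig(interval=GenomicInterval("9", 1, 100))
        stages = funnel.make_standard_snv_stages(config, panels, es)
        assert len(stages) == 8
        assert stages[0].kind == "quality"
        assert stages[0].param_dict == {"mq_min": 45.0, "dp_min": 10}
        assert [s.kind for s in stages] == [
            "quality", "shared_affected", "known_subtraction", "chromosome",
            "interval", "exonic", "nonsynonymous", "ancestral_subtraction",
        ]
        assert stages == funnel.make_standard_snv_stages(config, panels, es)

    def test_missing_panels_is_configuration_error(self):
        _, es = self._panels()
        config = funnel.FunnelConfig(interval=GenomicInterval("9", 1, 100))
        with pytest.raises(ValueError, match="panel"):
            funnel.make_standard_snv_stages(config, [], es)
        panels, _ = self._panels()
        with pytest.raises(ValueError, match="ES-line"):
            funnel.make_standard_snv_stages(config, panels, None)

    def test_disabled_thresholds_pass_everything(self):
        stage = funnel.FilterStage("q", "quality", (("mq_min", 0.0), ("dp_min", 0)))
        records = [_record(1, mq=0.0, dp=0), _record(2, mq=99.0, dp=500)]
        assert funnel.apply_stage(stage, records, funnel.FunnelContext()) == records

    def test_unknown_stage_kind_is_error(self):
        with pytest.raises(ValueError, match="unknown stage kind"):
            funnel.FilterStage("x", "wibble")


class TestStageSemantics:
    def test_quality_boundary_inclusive(self):
        stage = funnel.FilterStage("q", "quality", (("mq_min", 45.0), ("dp_min", 10)))
        at_boundary = _record(1, mq=45.0, dp=10)
        below = _record(2, mq=44.99, dp=10)
        shallow = _record(3, mq=60.0, dp=9)
        out = funnel.apply_stage(stage, [at_boundary, below, shallow],
                                 funnel.FunnelContext())
        assert out == [at_boundary]

    def test_shared_affected_requires_both_non_hom_ref(self):
        shared = (_record(100), _record(100))
        private = (_record(200),)
        ref_call = (_record(300), _record(300, genotypes={"A2": HOM_REF}))
        het_kept = (_record(400, genotypes={"A1": HET}),
                    _record(400, genotypes={"A2": HET}))
        cs1, cs2 = _affected_pair(
            [shared[0], private[0], ref_call[0], het_kept[0]],
            [shared[1], ref_call[1], het_kept[1]],
        )
        context = funnel.FunnelContext(affected=(cs1, cs2))
        stage = funnel.FilterStage("s", "shared_affected")
        survivors = funnel.apply_stage(
            stage, [shared[0], private[0], ref_call[0], het_kept[0]], context
        )
        assert [v.pos for v in survivors] == [100, 400]

    def test_known_subtraction_is_allele_aware(self):
        panel = CallSet(sample_id="db", role="known_db")
        panel.add(_record(100, ref="A", alt="C"))
        context = funnel.FunnelContext(panels=[panel])
        stage = funnel.FilterStage("k", "known_subtraction")
        same_allele = _record(100, ref="A", alt="C")
        other_allele = _record(100, ref="A", alt="G")
        assert funnel.apply_stage(stage, [same_allele, other_allele], context) == [
            other_allele
        ]

    def test_interval_containment_closed(self):
        stage = funnel.FilterStage(
            "i", "interval", (("interval", GenomicInterval("9", 100, 200)),)
        )
        records = [_record(99), _record(100), _record(200), _record(201)]
        survivors = funnel.apply_stage(stage, records, funnel.FunnelContext())
        assert [v.pos for v in survivors] == [100, 200]

    def test_ancestral_subtraction_on_published_records(self):
        """The ES-line flags remove the Taf1d, Col5a3 and Bmper records and
        keep the S1pr2 candidate."""
        records = fixtures.candidate_snv_records()
        context = funnel.FunnelContext(es_line=fixtures.candidate_snv_es_line())
        stage = funnel.FilterStage("es", "ancestral_subtraction")
        survivors = funnel.apply_stage(stage, records, context)
        kept = {v.annotations["gene"] for v in survivors}
        assert kept == {"Fat3", "Zfp426", "Rdh8", "S1pr2"}

    @pytest.mark.parametrize("kind,params", [
        ("quality", (("mq_min", 45.0), ("dp_min", 10))),
        ("chromosome", (("chrom", "9"),)),
        ("interval", (("interval", GenomicInterval("9", 1, 10)),)),
        ("exonic", ()),
        ("nonsynonymous", ()),
        ("known_subtraction", ()),
    ])
    def test_empty_input_yields_empty_output(self, kind, params):
        stage = funnel.FilterStage("x", kind, params)
        assert funnel.apply_stage(stage, [], funnel.FunnelContext()) == []


class TestSnvFunnel:
    def test_simulated_screen_audit_is_complete(self, tiny_config, tiny_world):
        genome, genes = tiny_world
        cs = synthetic.simulate_exome_callsets(tiny_config, genome, genes)
        interval = GenomicInterval("9", 20_000, 40_000)
        report = funnel.run_snv_funnel(
            cs.affected, [cs.known_db, cs.strain_panel], cs.es_line,
            interval, genes, genome,
        )
        universe = set(cs.affected[0].records) | set(cs.affected[1].records)
        assert set(report.audit) == universe
        assert sum(v == "passed" for v in report.audit.values()) == len(
            report.survivors
        )
        counts = [c for _, c in report.stage_counts]
        assert counts == sorted(counts, reverse=True)

    def test_final_set_is_stage_order_invariant(self, tiny_config, tiny_world):
        """Stages are pure predicates given fixed context, so the surviving
        SET does not depend on stage order."""
        genome, genes = tiny_world
        cs = synthetic.simulate_exome_callsets(tiny_config, genome, genes)
        interval = GenomicInterval("9", 20_000, 40_000)
        config = funnel.FunnelConfig(chrom="9", interval=interval)
        stages = funnel.make_standard_snv_stages(
            config, [cs.known_db, cs.strain_panel], cs.es_line
        )
        context = funnel.FunnelContext(
            affected=cs.affected, panels=[cs.known_db, cs.strain_panel],
            es_line=cs.es_line, genes=genes, genome=genome,
        )
        universe = {}
        for callset in cs.affected:
            for rec in callset:
                universe.setdefault(rec.key, rec)
        baseline = {
            v.key for v in funnel.run_stages(stages, list(universe.values()),
                                             context).survivors
        }
        rng = np.random.default_rng(1)
        for _ in range(5):
            order = rng.permutation(len(stages))
            permuted = [stages[i] for i in order]
            got = {
                v.key for v in funnel.run_stages(permuted, list(universe.values()),
                                                 context).survivors
            }
            assert got == baseline

    def test_funnel_on_zero_variants(self):
        aff = _affected_pair([], [])
        panel = CallSet(sample_id="db", role="known_db")
        es = CallSet(sample_id="es", role="es_line")
        report = funnel.run_snv_funnel(
            aff, [panel], es, GenomicInterval("9", 1, 100)
        )
        assert all(count == 0 for _, count in report.stage_counts)
        assert report.survivors == []

    def test_single_affected_callset_is_error(self):
        cs = CallSet(sample_id="A1", role="affected")
        with pytest.raises(ValueError, match="both affected"):
            funnel.run_snv_funnel(
                [cs], [CallSet(sample_id="db", role="known_db")],
                CallSet(sample_id="es", role="es_line"),
                GenomicInterval("9", 1, 100),
            )

    def test_monotonicity_violation_raises(self):
        with pytest.raises(AssertionError, match="non-increasing"):
            funnel.FunnelReport(
                stage_counts=[("a", 1), ("b", 2)], survivors=[], audit={}
            )


class TestIndelFunnel:
    def test_published_indels_evidence(self):
        """The four published deletions: none in coding sequence, two carried
        by the ancestral ES line."""
        evidence = funnel.indel_evidence(
            fixtures.indel_records(), es_line=fixtures.indel_es_line()
        )
        assert evidence["coding_region_count"] == 0
        assert evidence["es_line_count"] == 2
        es_genes = {
            k[1] for k in evidence["es_line_keys"]
        }
        assert es_genes == {21_149_853, 21_786_028}  # Slc44a2, Rgl3 positions

    def test_single_survivor_above_mean_quality(self):
        """With one high-quality indel among low-quality ones, the quality
        stage alone leaves a single survivor."""
        quals = [10.0, 10.0, 10.0, 100.0]
        recs1 = [_record(1000 + i, ref="AC", alt="A", qual=q,
                         annotations={"location": "intronic", "is_cds": "0"})
                 for i, q in enumerate(quals)]
        recs2 = [_record(1000 + i, ref="AC", alt="A", qual=q,
                         annotations={"location": "intronic", "is_cds": "0"})
                 for i, q in enumerate(quals)]
        cs1, cs2 = _affected_pair(recs1, recs2)
        report = funnel.run_indel_funnel(
            (cs1, cs2), GenomicInterval("9", 1, 10_000)
        )
        assert len(report.survivors) == 1
        assert report.survivors[0].pos == 1003

    def test_out_of_interval_indel_decoys_never_survive(
        self, tiny_config, tiny_world
    ):
        genome, genes = tiny_world
        cs = synthetic.simulate_exome_callsets(tiny_config, genome, genes)
        interval = GenomicInterval("9", 20_000, 40_000)
        report = funnel.run_indel_funnel(
            cs.affected, interval, es_line=cs.es_line, genes=genes, genome=genome
        )
        for survivor in report.survivors:
            assert interval.contains(survivor.chrom, survivor.pos)
        assert report.extras["coding_region_count"] == 0
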