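"""bgc_io: GenBank/MIBiG parsing, filtering, trimming, classification, BDAs."""

import dataclasses

import pytest

from bdakit import bgc_io
from bdakit.bgc_io import (
    BGCParseError,
    BGCRecord,
    DomainCall,
    FilterConfig,
    MIBiGRejection,
    build_bda,
    classify_reference,
    filter_short_contigs,
    flag_contig_edge,
    map_product_to_class,
    normalize_label,
    parse_antismash_genbank,
    parse_mibig_json,
    resolve_feature_precedence,
    trim_region,
)
from bdakit.synthetic_fixtures import generate_genbank, generate_mibig_json, make_bgc_record


def _record(**kw) -> BGCRecord:
    defaults = dict(
        bgc_id="b1", contig_id="c1", contig_length=100_000, bgc_class="NRPS",
        subclass=["NRPS"], region_start=0, region_end=50_000,
    )
    defaults.update(kw)
    return BGCRecord(**defaults)


def _call(label="AMP_binding", cds="cds0", start=100, end=400, kind="NRPS_PKS",
          strand="+", rank=0) -> DomainCall:
    return DomainCall(label, cds, strand, start, end, kind, rank)


class TestGenBankParsing:
    def test_one_region_two_cds(self):
        rec = make_bgc_record("b1", ("AMP_binding", "PCP"), cds_split=[1, 1])
        parsed = parse_antismash_genbank(generate_genbank([rec]))
        assert len(parsed) == 1
        assert [d.label for d in parsed[0].domains] == ["AMP_binding", "PCP"]
        assert parsed[0].contig_length == rec.contig_length

    def test_cds_with_both_qualifier_kinds_retains_both(self):
        nrps = make_bgc_record("b1", ("AMP_binding",))
        both = dataclasses.replace(
            nrps,
            domains=nrps.domains
            + [
                DomainCall(
                    "Chal_sti_synt_N",
                    nrps.domains[0].cds_id,
                    "+",
                    nrps.domains[0].start,
                    nrps.domains[0].end,
                    "sec_met_domain",
                    0,
                )
            ],
        )
        parsed = parse_antismash_genbank(generate_genbank([both]))
        kinds = {d.source_feature for d in parsed[0].domains}
        assert kinds == {"NRPS_PKS", "sec_met_domain"}

    def test_region_without_product_warns_and_maps_to_other(self):
        rec = make_bgc_record("b1", ("AMP_binding",), subclasses=())
        with pytest.warns(UserWarning, match="no 'product'"):
            parsed = parse_antismash_genbank(generate_genbank([rec]))
        assert parsed[0].bgc_class == "other"

    def test_malformed_input_raises_parse_error(self):
        with pytest.raises(BGCParseError):
            parse_antismash_genbank("not genbank at all\n")

    def test_round_trip_preserves_domains_and_coordinates(self):
        recs = [
            make_bgc_record("b1", ("Cond_LCL", "AMP_binding", "PCP", "TE"),
                            cds_split=[3, 1], strands=["+", "-"], contig_id="c1"),
            make_bgc_record("b2", ("Itr_KS", "AT", "KR"), contig_id="c2",
                            source_feature="sec_met_domain", subclasses=("T3PKS",)),
        ]
        parsed = parse_antismash_genbank(generate_genbank(recs))
        assert len(parsed) == len(recs)
        for orig, back in zip(recs, parsed):
            assert [(d.label, d.start, d.end, d.strand, d.rank_in_cds, d.source_feature)
                    for d in orig.domains] == [
                (d.label, d.start, d.end, d.strand, d.rank_in_cds, d.source_feature)
                for d in back.domains
            ]
            assert (back.region_start, back.region_end) == (orig.region_start, orig.region_end)


class TestClassification:
    @pytest.mark.parametrize(
        "products, expected",
        [
            (["NRPS-like"], "NRPS"),
            (["NRPS"], "NRPS"),
            (["T1PKS"], "modular_PKS"),
            (["T2PKS"], "modular_PKS"),
            (["T3PKS"], "typeIII_PKS"),
            (["terpene"], "TPS"),
            (["lanthipeptide"], "other"),
            (["NRPS", "T1PKS"], "NRPS"),  # hybrid defaults to NRPS
            (["T1PKS", "terpene"], "modular_PKS"),
        ],
    )
    def test_product_to_class(self, products, expected):
        assert map_product_to_class(products) == expected

    def test_hybrid_with_iterative_ks_forces_modular_pks(self):
        assert map_product_to_class(["NRPS", "T1PKS"], ["Itr_KS", "PCP"]) == "modular_PKS"
        # without the iterative KS the hybrid stays NRPS
        assert map_product_to_class(["NRPS", "T1PKS"], ["Mod_KS", "PCP"]) == "NRPS"

    def test_empty_products_rejected(self):
        with pytest.raises(ValueError):
            map_product_to_class([])

    @pytest.mark.parametrize(
        "biosyn, sub, expected",
        [
            (["NRP", "Polyketide"], ["Type I"], {"NRPS", "modular_PKS"}),
            (["Polyketide"], ["Type III"], {"typeIII_PKS"}),
            (["Terpene"], [], {"TPS"}),
            (["NRP"], [], {"NRPS"}),
            (["Polyketide"], [], {"modular_PKS"}),
            (["Alkaloid"], [], set()),
        ],
    )
    def test_classify_reference(self, biosyn, sub, expected):
        assert classify_reference(biosyn, sub) == expected

    def test_type_iii_only_never_modular(self):
        for sub in (["Type III"], ["type III"], ["Type-III"]):
            assert "modular_PKS" not in classify_reference(["Polyketide"], sub)


class TestPrecedence:
    def _both_kinds(self):
        return [
            _call("AMP_binding", "cdsA", kind="NRPS_PKS"),
            _call("Chal_sti_synt_N", "cdsA", kind="sec_met_domain"),
            _call("PCP", "cdsB", start=500, end=800, kind="sec_met_domain"),
        ]

    def test_nrps_record_keeps_nrps_pks(self):
        out = resolve_feature_precedence(self._both_kinds(), "NRPS")
        assert [(c.cds_id, c.source_feature) for c in out] == [
            ("cdsA", "NRPS_PKS"), ("cdsB", "sec_met_domain")
        ]

    def test_tps_record_keeps_sec_met(self):
        out = resolve_feature_precedence(self._both_kinds(), "TPS")
        assert all(c.source_feature == "sec_met_domain" for c in out)

    def test_single_kind_kept_regardless(self):
        calls = [_call("PCP", "cdsB", kind="sec_met_domain")]
        assert resolve_feature_precedence(calls, "NRPS") == calls


class TestTrimAndFilter:
    def test_trim_to_domain_bearing_span(self):
        rec = _record(region_start=0, region_end=50_000,
                      domains=[_call(start=12_000, end=30_000)])
        trimmed = trim_region(rec)
        assert (trimmed.region_start, trimmed.region_end) == (12_000, 30_000)

    def test_trim_identity_when_all_cds_bear_domains(self):
        rec = _record(region_start=12_000, region_end=30_000,
                      domains=[_call(start=12_000, end=30_000)])
        trimmed = trim_region(rec)
        assert (trimmed.region_start, trimmed.region_end) == (12_000, 30_000)

    def test_trim_no_domains_flags(self):
        rec = _record(bgc_class="other")
        trimmed = trim_region(rec)
        assert "no_domains" in trimmed.flags
        assert (trimmed.region_start, trimmed.region_end) == (0, 50_000)

    @pytest.mark.parametrize(
        "start, end, length, expected",
        [
            (0, 5_000, 100_000, True),
            (30_000, 50_000, 100_000, False),
            (30_000, 50_000, 60_000, True),  # 3' margin starts at 40 kb
        ],
    )
    def test_contig_edge(self, start, end, length, expected):
        rec = _record(region_start=start, region_end=end, contig_length=length)
        assert flag_contig_edge(rec, FilterConfig()) is expected

    def test_short_contig_boundary(self):
        short = _record(contig_length=9_999)
        exact = _record(bgc_id="b2", contig_length=10_000)
        kept, removed = filter_short_contigs([short, exact])
        assert [r.bgc_id for r in kept] == ["b2"]
        assert [r.bgc_id for r in removed] == ["b1"]

    def test_filter_empty_input(self):
        assert filter_short_contigs([]) == ([], [])

    def test_filter_partitions_input(self, rng):
        records = [
            _record(bgc_id=f"b{i}", contig_length=int(rng.integers(5_000, 20_000)))
            for i in range(30)
        ]
        kept, removed = filter_short_contigs(records)
        assert sorted(r.bgc_id for r in kept + removed) == sorted(r.bgc_id for r in records)
        merged = {r.bgc_id for r in kept} & {r.bgc_id for r in removed}
        assert not merged

    def test_pipeline_idempotent(self):
        rec = _record(domains=[_call(start=25_000, end=30_000)])
        once, _ = bgc_io.postprocess([rec])
        twice, _ = bgc_io.postprocess(once)
        assert [(r.region_start, r.region_end, r.contig_edge) for r in once] == [
            (r.region_start, r.region_end, r.contig_edge) for r in twice
        ]


class TestMIBiG:
    def test_complete_with_evidence_accepted(self):
        out = parse_mibig_json(generate_mibig_json(evidence=("Knock-out studies",)))
        assert isinstance(out, list)
        assert out[0].role == "reference"
        assert out[0].evidence == ["Knock-out studies"]

    def test_complete_without_evidence_rejected(self):
        out = parse_mibig_json(generate_mibig_json(evidence=()))
        assert isinstance(out, MIBiGRejection)
        assert "evidence" in out.reason

    def test_incomplete_rejected(self):
        out = parse_mibig_json(generate_mibig_json(completeness="incomplete"))
        assert isinstance(out, MIBiGRejection)

    def test_missing_completeness_rejected_with_reason(self):
        out = parse_mibig_json('{"cluster": {"mibig_accession": "BGC1", "loci": {}}}')
        assert isinstance(out, MIBiGRejection)
        assert "completeness" in out.reason

    def test_absent_organism_tolerated(self):
        out = parse_mibig_json(generate_mibig_json(organism=None))
        assert out[0].organism == "unknown"

    def test_unparsable_json_raises(self):
        with pytest.raises(BGCParseError):
            parse_mibig_json("{not json")

    def test_non_exclusive_classes_yield_multiple_records(self):
        out = parse_mibig_json(
            generate_mibig_json(biosyn_class=("NRP", "Polyketide"), pks_subclasses=("Type I",))
        )
        assert {r.bgc_class for r in out} == {"NRPS", "modular_PKS"}


class TestBDA:
    def test_plus_strand_cds_order(self):
        rec = make_bgc_record("b1", ("Cond_LCL", "AMP_binding", "PCP", "TE"),
                              cds_split=[3, 1])
        assert build_bda(rec).tokens == ("Cond_LCL", "AMP_binding", "PCP", "TE")

    def test_minus_strand_translation_order(self):
        # genomic order on the contig reads PCP, AMP_binding, Cond_LCL but the
        # minus-strand translation order is condensation first
        rec = make_bgc_record("b1", ("Cond_LCL", "AMP_binding", "PCP"), strands=["-"])
        genomic = sorted(rec.domains, key=lambda d: d.start)
        assert [d.label for d in genomic] == ["PCP", "AMP_binding", "Cond_LCL"]
        assert build_bda(rec).tokens == ("Cond_LCL", "AMP_binding", "PCP")

    def test_six_token_candidate_architecture(self):
        tokens = ("Cond_LCL", "AMP_binding", "PP_bind", "Cond_LCL", "AMP_binding", "PCP")
        rec = make_bgc_record("MesVir_RPFO01000156.1_1", tokens, cds_split=[3, 3])
        assert build_bda(rec).tokens == tokens

    def test_modular_record_without_domains_is_error(self):
        rec = _record(bgc_class="NRPS", domains=[])
        with pytest.raises(ValueError, match="no biosynthetic domains"):
            build_bda(rec)

    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("PP-binding", "PP_bind"),
            (" AMP-binding ", "AMP_binding"),
            ("Condensation_LCL", "Cond_LCL"),
            ("PP binding", "PP_bind"),
            ("Thioesterase", "TE"),
        ],
    )
    def test_label_normalization(self, raw, expected):
        assert normalize_label(raw) == expected
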