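"""Promoter part design: extraction rules, site scanning, domestication, assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gemmatlas as g
from gemmatlas.parts import (
    ENZYMES,
    Acceptor,
    DesignRules,
    DomesticationError,
    Exclusion,
    annotation_stats,
    build_l0,
    design_parts,
    domesticate,
    extract_parts,
    gene_model,
    scan_sites,
    simulate_assembly,
    strip_flanks,
    _revcomp,
)

import gffutils

from conftest import N_RUN_GENE_INDEX, RULE_UTR_LENGTHS


def brute_scan(seq, enzymes=ENZYMES):
    hits = set()
    for name, site in enzymes.items():
        for strand, pat in (("+", site), ("-", _revcomp(site))):
            for i in range(len(seq) - len(pat) + 1):
                if seq[i : i + len(pat)] == pat:
                    hits.add((name, i + 1, strand))
    return hits


class TestScanSites:
    def test_plus_strand_hit_position(self):
        hits = scan_sites("AAGGTCTCAA")
        assert [(h.enzyme, h.position, h.strand) for h in hits] == [("BsaI", 3, "+")]

    def test_minus_strand_hit(self):
        hits = scan_sites("TTTGAGACCTTT")
        assert [(h.enzyme, h.position, h.strand) for h in hits] == [("BsaI", 4, "-")]

    def test_equals_exhaustive_sliding_window_oracle(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        ours = {(h.enzyme, h.position, h.strand) for h in scan_sites(seq)}
        assert ours == brute_scan(seq)

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            scan_sites("ACGTXACGT")


class TestDomesticate:
    def test_site_free_sequence_unchanged(self):
        seq = "ATATATCGCGCGATCGATTACA" * 10
        out, edits = domesticate(seq)
        assert out == seq and edits == []

    def test_single_site_removed_with_one_edit(self):
        seq = "A" * 50 + "GGTCTC" + "T" * 50
        out, edits = domesticate(seq)
        assert scan_sites(out) == []
        assert len(edits) == 1
        hamming = sum(a != b for a, b in zip(seq, out))
        assert hamming == 1

    def test_edit_list_replays_onto_source(self):
        seq = "C" * 30 + "GCTCTTC" + "A" * 30 + "GAGACC" + "T" * 30
        out, edits = domesticate(seq)
        replayed = list(seq)
        for pos, old, new in edits:
            assert replayed[pos - 1] == old
            replayed[pos - 1] = new
        assert "".join(replayed) == out

    @given(st.integers(0, 10**6), st.integers(1, 5))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_random_planted_sites_always_cleared(self, seed, n_sites):
        rng = np.random.default_rng(seed)
        seq = list(rng.choice(list("ACGT"), size=600))
        sites = list(ENZYMES.values()) + [_revcomp(s) for s in ENZYMES.values()]
        for i in range(n_sites):
            pos = 20 + i * 110 + int(rng.integers(0, 60))
            site = sites[int(rng.integers(0, len(sites)))]
            seq[pos : pos + len(site)] = list(site)
        out, edits = domesticate("".join(seq))
        assert scan_sites(out) == []
        assert len(out) == 600
        assert len(edits) <= 3 * len(scan_sites("".join(seq)))

    def test_ambiguous_bases_rejected(self):
        with pytest.raises(ValueError, match="A, C, G, T"):
            domesticate("ACGTNACGT")


class TestExtractParts:
    def test_rule_table_on_toy_genome(self, rule_genome, rule_db):
        outcomes = {}
        for gid in rule_genome.gene_ids:
            outcomes[gid] = extract_parts(rule_genome.sequences, rule_db, gid)
        by_utr = {rule_genome.utr_lengths[gid]: r for gid, r in outcomes.items()}
        assert [p.part_type for p in by_utr[100]] == ["PROM5"]
        assert [p.part_type for p in by_utr[499]] == ["PROM5"]
        assert [p.part_type for p in by_utr[500]] == ["PROM", "5UTR"]
        assert [p.part_type for p in by_utr[2999]] == ["PROM", "5UTR"]
        assert [p.part_type for p in by_utr[3000]] == ["PROM", "5UTR"]
        assert isinstance(by_utr[3500], Exclusion)
        assert by_utr[3500].reason == "utr_too_long"
        n_run_gene = rule_genome.gene_ids[N_RUN_GENE_INDEX]
        assert isinstance(outcomes[n_run_gene], Exclusion)
        assert outcomes[n_run_gene].reason == "n_run_in_promoter"

    def test_part_lengths_and_coordinates(self, rule_genome, rule_db):
        # PROM5 = 1800 upstream + UTR; PROM = 1800; 5UTR = UTR length
        for gid in rule_genome.gene_ids:
            result = extract_parts(rule_genome.sequences, rule_db, gid)
            if isinstance(result, Exclusion):
                continue
            utr = rule_genome.utr_lengths[gid]
            if utr < 500:
                (p,) = result
                assert len(p.sequence) == 1800 + utr
            else:
                prom, five = result
                assert len(prom.sequence) == 1800
                assert len(five.sequence) == utr

    def test_plus_strand_coordinate_oracle(self):
        # TSS at 3001, translation start 3301 -> one PROM5 spanning 1201..3300
        tg = g.make_toy_genome([300], seed=7, upstream_margin=3000)
        db = gffutils.create_db(tg.gff_text, ":memory:", from_string=True, force=True, keep_order=True)
        gid = tg.gene_ids[0]
        model = gene_model(db, gid)
        assert model.strand == "+"
        (part,) = extract_parts(tg.sequences, db, gid)
        assert part.part_type == "PROM5"
        assert (part.start, part.end) == (model.tss - 1800, model.translation_start - 1)
        assert len(part.sequence) == 2100
        assert part.sequence == tg.sequences["chr1"][part.start - 1 : part.end]

    def test_minus_strand_is_reverse_complement(self, rule_genome, rule_db):
        minus = [gid for gid, s in rule_genome.strands.items() if s == "-"]
        for gid in minus:
            result = extract_parts(rule_genome.sequences, rule_db, gid)
            if isinstance(result, Exclusion):
                continue
            for part in result:
                plus_slice = rule_genome.sequences[part.seqid][part.start - 1 : part.end]
                assert part.sequence == _revcomp(plus_slice)
                for a, b in zip(part.sequence, reversed(plus_slice)):
                    assert a == {"A": "T", "T": "A", "C": "G", "G": "C"}[b]

    def test_truncated_upstream_window_warns(self):
        tg = g.make_toy_genome([100], seed=8, upstream_margin=2500)
        # fabricate a gene too close to the contig start by shifting annotation
        gff = tg.gff_text.replace("2501", "901").replace("2601", "1001").replace("2900", "1300")
        db = gffutils.create_db(gff, ":memory:", from_string=True, force=True, keep_order=True)
        with pytest.warns(UserWarning, match="truncated"):
            result = extract_parts(tg.sequences, db, tg.gene_ids[0])
        (part,) = result
        assert part.truncated
        assert part.start == 1

    def test_strand_symmetry(self, rule_genome, rule_db):
        """Reverse-complementing the contig and flipping the annotation yields
        identical part sequences."""
        seq = rule_genome.sequences["chr1"]
        L = len(seq)
        flipped_seq = {"chr1": _revcomp(seq)}
        lines = []
        for line in rule_genome.gff_text.strip().split("\n"):
            if line.startswith("#"):
                lines.append(line)
                continue
            f = line.split("\t")
            start, end = int(f[3]), int(f[4])
            f[3], f[4] = str(L - end + 1), str(L - start + 1)
            f[6] = {"+": "-", "-": "+"}[f[6]]
            lines.append("\t".join(f))
        db2 = gffutils.create_db(
            "\n".join(lines) + "\n", ":memory:", from_string=True, force=True, keep_order=True
        )
        for gid in rule_genome.gene_ids:
            a = extract_parts(rule_genome.sequences, rule_db, gid)
            b = extract_parts(flipped_seq, db2, gid)
            if isinstance(a, Exclusion):
                assert isinstance(b, Exclusion) and a.reason == b.reason
            else:
                assert [(p.part_type, p.sequence) for p in a] == [
                    (p.part_type, p.sequence) for p in b
                ]


class TestL0AndAssembly:
    def _domesticated_part(self, rule_genome, rule_db, gid):
        result = extract_parts(rule_genome.sequences, rule_db, gid)
        parts = []
        from dataclasses import replace

        for p in result:
            seq, edits = domesticate(p.sequence)
            parts.append(replace(p, sequence=seq, edits=edits))
        return parts

    def test_fusion_sites_per_part_type(self, rule_genome, rule_db):
        gid500 = next(g_ for g_, u in rule_genome.utr_lengths.items() if u == 500)
        prom, five = self._domesticated_part(rule_genome, rule_db, gid500)
        l0_prom = build_l0(prom)
        l0_five = build_l0(five)
        assert (l0_prom.fusion5, l0_prom.fusion3) == ("GGAG", "TACT")
        assert (l0_five.fusion5, l0_five.fusion3) == ("TACT", "AATG")
        assert l0_prom.sequence.startswith("GGTCTCAGGAG")
        assert l0_prom.sequence.endswith("TACT" + "TGAGACC")

    def test_prom5_flanks(self, rule_genome, rule_db):
        gid100 = next(g_ for g_, u in rule_genome.utr_lengths.items() if u == 100)
        (p5,) = self._domesticated_part(rule_genome, rule_db, gid100)
        rec = build_l0(p5)
        assert (rec.fusion5, rec.fusion3) == ("GGAG", "AATG")

    def test_strip_flanks_round_trip(self, rule_genome, rule_db):
        gid100 = next(g_ for g_, u in rule_genome.utr_lengths.items() if u == 100)
        (p5,) = self._domesticated_part(rule_genome, rule_db, gid100)
        rec = build_l0(p5)
        assert strip_flanks(rec) == p5.sequence

    def test_undomesticated_part_rejected(self, rule_genome, rule_db):
        gid100 = next(g_ for g_, u in rule_genome.utr_lengths.items() if u == 100)
        (raw,) = extract_parts(rule_genome.sequences, rule_db, gid100)
        if scan_sites(raw.sequence):  # the planted BsaI site is in this promoter
            with pytest.raises(ValueError, match="enzyme sites"):
                build_l0(raw)

    def test_compatible_chain_assembles(self, rule_genome, rule_db):
        gid500 = next(g_ for g_, u in rule_genome.utr_lengths.items() if u == 500)
        prom, five = self._domesticated_part(rule_genome, rule_db, gid500)
        parts = [build_l0(prom), build_l0(five)]
        acceptor = Acceptor("GGAG", "AATG", backbone="T" * 100)
        out = simulate_assembly(acceptor, parts)
        assert out["success"]
        assert out["order"] == [parts[0].name, parts[1].name]
        # junction accounting: backbone + cores + one fusion per junction
        cores = sum(len(strip_flanks(p)) for p in parts)
        assert out["length"] == 100 + cores + 4 * (len(parts) + 1)

    def test_duplicate_overhangs_fail(self, rule_genome, rule_db):
        gid100 = next(g_ for g_, u in rule_genome.utr_lengths.items() if u == 100)
        gid499 = next(g_ for g_, u in rule_genome.utr_lengths.items() if u == 499)
        (a,) = self._domesticated_part(rule_genome, rule_db, gid100)
        (b,) = self._domesticated_part(rule_genome, rule_db, gid499)
        out = simulate_assembly(Acceptor("GGAG", "AATG"), [build_l0(a), build_l0(b)])
        assert not out["success"]
        assert any("duplicate overhang GGAG" in e for e in out["errors"])

    def test_unmatched_overhang_fail(self, rule_genome, rule_db):
        gid500 = next(g_ for g_, u in rule_genome.utr_lengths.items() if u == 500)
        prom, _ = self._domesticated_part(rule_genome, rule_db, gid500)
        out = simulate_assembly(Acceptor("GGAG", "AATG"), [build_l0(prom)])
        assert not out["success"]

    def test_design_parts_emits_site_free_records(self, rule_genome, rule_db):
        records, exclusions = design_parts(
            rule_genome.sequences, rule_db, rule_genome.gene_ids
        )
        assert len(exclusions) == 2
        assert len(records) == 2 * 1 + 3 * 2  # two PROM5 + three PROM/5UTR pairs
        for rec in records:
            assert scan_sites(strip_flanks(rec)) == []


class TestAnnotationStats:
    def test_toy_medians(self, rule_db, rule_genome):
        stats = annotation_stats(rule_db)
        utrs = stats["utr_lengths"].set_index("gene_id")["utr_length"]
        for gid, expected in rule_genome.utr_lengths.items():
            assert utrs[gid] == expected
        assert stats["median_utr"] == float(np.median(RULE_UTR_LENGTHS))

    def test_intergenic_gap_arithmetic(self):
        gff = "\n".join(
            [
                "##gff-version 3",
                "chr1\tt\tgene\t1\t1000\t.\t+\t.\tID=ga",
                "chr1\tt\tmRNA\t1\t1000\t.\t+\t.\tID=ga.1;Parent=ga",
                "chr1\tt\tCDS\t500\t1000\t.\t+\t0\tID=ga.1.c;Parent=ga.1",
                "chr1\tt\tgene\t2001\t3000\t.\t+\t.\tID=gb",
                "chr1\tt\tmRNA\t2001\t3000\t.\t+\t.\tID=gb.1;Parent=gb",
                "chr1\tt\tCDS\t2500\t3000\t.\t+\t0\tID=gb.1.c;Parent=gb.1",
            ]
        ) + "\n"
        db = gffutils.create_db(gff, ":memory:", from_string=True, force=True, keep_order=True)
        stats = annotation_stats(db)
        assert list(stats["intergenic_lengths"]["length"]) == [1000]

    def test_overlapping_genes_count_as_zero(self):
        gff = "\n".join(
            [
                "##gff-version 3",
                "chr1\tt\tgene\t1\t1000\t.\t+\t.\tID=ga",
                "chr1\tt\tmRNA\t1\t1000\t.\t+\t.\tID=ga.1;Parent=ga",
                "chr1\tt\tCDS\t500\t1000\t.\t+\t0\tID=ga.1.c;Parent=ga.1",
                "chr1\tt\tgene\t900\t1800\t.\t-\t.\tID=gb",
                "chr1\tt\tmRNA\t900\t1800\t.\t-\t.\tID=gb.1;Parent=gb",
                "chr1\tt\tCDS\t900\t1400\t.\t-\t0\tID=gb.1.c;Parent=gb.1",
            ]
        ) + "\n"
        db = gffutils.create_db(gff, ":memory:", from_string=True, force=True, keep_order=True)
        stats = annotation_stats(db)
        assert list(stats["intergenic_lengths"]["length"]) == [0]

    def test_medians_match_sort_and_middle_oracle(self):
        rng = np.random.default_rng(9)
        lengths = [int(v) for v in rng.integers(10, 800, size=9)]
        tg = g.make_toy_genome(lengths, seed=10)
        db = gffutils.create_db(tg.gff_text, ":memory:", from_string=True, force=True, keep_order=True)
        stats = annotation_stats(db)
        s = sorted(lengths)
        assert stats["median_utr"] == s[len(s) // 2]
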