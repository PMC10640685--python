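import random

import pytest

from kmersnp.annotation import (
    NA,
    load_annotated_genomes,
    annotate_matrix,
    annotate_snp,
    locate_snp,
    locus_verdict,
    write_annotation_reports,
)
from kmersnp.genome_io import GenomeRecord
from kmersnp.kmer_engine import revcomp
from kmersnp.snp_discovery import find_snps
from kmersnp.synthetic_data import synth_genbank
from Bio.Seq import Seq

K = 9


def _family_with_cds(rng, substitutions, length=900, cds=None):
    """Two genomes differing at given (pos, base_a, base_b) sites (1-based)."""
    seq = list(rng.choice("ACGT") for _ in range(length))
    for pos, a, _ in substitutions:
        seq[pos - 1] = a
    seq_a = "".join(seq)
    for pos, _, b in substitutions:
        seq[pos - 1] = b
    seq_b = "".join(seq)
    ga = GenomeRecord(genome_id="ga", sequences=[("ga", seq_a)])
    gb = GenomeRecord(genome_id="gb", sequences=[("gb", seq_b)])
    return ga, gb


def _annotated(tmp_path, genome, cds_spec):
    synth_genbank(genome, cds_spec, tmp_path / f"{genome.genome_id}.gbk")
    listfile = tmp_path / "annotated"
    listfile.write_text(genome.genome_id + "\n")
    (ann,) = load_annotated_genomes(listfile, tmp_path, [genome])
    return ann


def test_synonymous_and_nonsynonymous_calls(tmp_path, rng):
    # CDS 301..600 in frame; codon at 451..453 is GAx
    subs = [(453, "A", "G"), (500, "A", "T")]
    ga, gb = _family_with_cds(rng, subs)
    # force the codon context: positions 451..453 = GAA in ga, GAG in gb
    sa = list(ga.sequences[0][1]); sb = list(gb.sequences[0][1])
    sa[450:453] = "GAA"; sb[450:453] = "GAG"
    # second codon 499..501: GAA in ga -> GTA in gb (second position)
    sa[498:501] = "GAA"; sb[498:501] = "GTA"
    ga = GenomeRecord(genome_id="ga", sequences=[("ga", "".join(sa))])
    gb = GenomeRecord(genome_id="gb", sequences=[("gb", "".join(sb))])
    matrix = find_snps([ga, gb], K)
    cds = [{"start": 301, "end": 600, "strand": 1, "product": "demo protein"}]
    ann_a = _annotated(tmp_path, ga, cds)
    by_pos = {}
    for locus in matrix.loci:
        for rec in annotate_snp(locus, ann_a):
            by_pos[rec.position] = rec
    rec_syn = by_pos[453]
    assert rec_syn.within_cds and rec_syn.codon == "GAA"
    assert rec_syn.amino_acid == "E"
    assert rec_syn.synonymy == "synonymous"  # GAA vs GAG both Glu
    rec_non = by_pos[500]
    assert rec_non.codon == "GAA" and rec_non.synonymy == "nonsynonymous"
    # translating the reported codon always yields the reported amino acid
    for rec in by_pos.values():
        if rec.codon != NA:
            assert str(Seq(rec.codon).translate(table=11)) == rec.amino_acid


def test_intergenic_and_peptide_window(tmp_path, rng):
    subs = [(50, "A", "G"), (450, "C", "T")]
    ga, gb = _family_with_cds(rng, subs)
    matrix = find_snps([ga, gb], K)
    cds = [{"start": 301, "end": 600, "strand": 1, "product": "demo"}]
    ann_a = _annotated(tmp_path, ga, cds)
    rows = [r for l in matrix.loci for r in annotate_snp(l, ann_a)]
    by_pos = {r.position: r for r in rows}
    assert by_pos[50].synonymy == "intergenic"
    assert by_pos[50].product == NA
    inside = by_pos[450]
    assert inside.within_cds
    assert 1 <= len(inside.peptide_context) <= 11
    assert inside.amino_acid in inside.peptide_context


def test_minus_strand_cds_codon_in_reading_frame(tmp_path, rng):
    """A SNP inside a minus-strand CDS is reported in the CDS frame: the
    codon contains the reverse-complemented allele and translates to the
    reported amino acid under the same table."""
    subs = [(450, "A", "G")]
    ga, gb = _family_with_cds(rng, subs)
    matrix = find_snps([ga, gb], K)
    cds = [{"start": 301, "end": 600, "strand": -1, "product": "rev demo"}]
    ann_a = _annotated(tmp_path, ga, cds)
    rows = [r for l in matrix.loci for r in annotate_snp(l, ann_a)]
    rec = next(r for r in rows if r.position == 450)
    assert rec.within_cds
    seq = ga.sequences[0][1]
    # codon is read on the minus strand: the SNP base appears complemented
    # at its in-codon offset (position 450 inside CDS 301..600 on '-')
    idx_in_cds = 600 - 450  # coding order runs end -> start
    assert rec.codon[idx_in_cds % 3] == revcomp(seq[449])
    assert str(Seq(rec.codon).translate(table=11)) == rec.amino_acid


def test_revcomp_genome_annotation_invariant(tmp_path, rng):
    """Annotating the reverse-complemented genome (with mirrored CDS
    coordinates) yields the identical codon and amino acid."""
    subs = [(450, "A", "G")]
    ga, gb = _family_with_cds(rng, subs)
    L = ga.total_length
    matrix = find_snps([ga, gb], K)
    cds_fwd = [{"start": 301, "end": 600, "strand": 1, "product": "demo"}]
    ann_fwd = _annotated(tmp_path, ga, cds_fwd)
    rows_fwd = [r for l in matrix.loci for r in annotate_snp(l, ann_fwd)]
    rec_fwd = next(r for r in rows_fwd if r.position == 450)

    ga_rc = GenomeRecord(
        genome_id="ga", sequences=[("ga", revcomp(ga.sequences[0][1]))]
    )
    matrix_rc = find_snps([ga_rc, gb], K)
    dir2 = tmp_path / "rc"
    dir2.mkdir()
    cds_rc = [
        {"start": L - 600 + 1, "end": L - 301 + 1, "strand": -1, "product": "demo"}
    ]
    ann_rc = _annotated(dir2, ga_rc, cds_rc)
    rows_rc = [r for l in matrix_rc.loci for r in annotate_snp(l, ann_rc)]
    rec_rc = next(r for r in rows_rc if r.position == L - 450 + 1)
    assert rec_rc.codon == rec_fwd.codon
    assert rec_rc.amino_acid == rec_fwd.amino_acid
    assert rec_rc.synonymy == rec_fwd.synonymy


def test_locate_snp_uses_discovery_positions(planted_fixture):
    records, truth, k = planted_fixture
    matrix = find_snps(records, k)
    locus = matrix.loci[0]
    for gid in matrix.genome_ids:
        got = locate_snp(locus, gid)
        assert got == locus.positions.get(gid, [])


def test_load_list_validation(tmp_path, rng):
    ga, gb = _family_with_cds(rng, [(100, "A", "G")], length=400)
    synth_genbank(ga, [], tmp_path / "ga.gbk")
    lf = tmp_path / "lst"
    lf.write_text("nope\n")
    with pytest.raises(ValueError, match="nope"):
        load_annotated_genomes(lf, tmp_path, [ga, gb])
    lf.write_text("gb\n")
    with pytest.raises(FileNotFoundError, match="gb"):
        load_annotated_genomes(lf, tmp_path, [ga, gb])
    lf.write_text("")
    assert load_annotated_genomes(lf, tmp_path, [ga, gb]) == []
    # sequence mismatch is an error naming the genome
    bad = GenomeRecord(genome_id="ga", sequences=[("ga", "ACGT" * 100)])
    lf.write_text("ga\n")
    with pytest.raises(ValueError, match="ga"):
        load_annotated_genomes(lf, tmp_path, [bad, gb])


def test_reports_row_counts(tmp_path, rng):
    ga, gb = _family_with_cds(rng, [(450, "A", "G")])
    matrix = find_snps([ga, gb], K)
    cds = [{"start": 301, "end": 600, "strand": 1, "product": "demo"}]
    synth_genbank(ga, cds, tmp_path / "ga.gbk")
    synth_genbank(gb, cds, tmp_path / "gb.gbk")
    lf = tmp_path / "annotated"
    lf.write_text("ga\ngb\n")
    anns = annotate_matrix(
        matrix, load_annotated_genomes(lf, tmp_path, [ga, gb])
    )
    summary, detail = write_annotation_reports(matrix, anns, tmp_path)
    assert len(summary.read_text().splitlines()) == 1 + matrix.n_loci
    n_rows = sum(len(v) for v in anns.values())
    assert len(detail.read_text().splitlines()) == 1 + n_rows
    # one locus annotated in 2 genomes: summary 1 row, detail 2 rows
    target = [v for v in anns.values() if len(v) == 2]
    assert target


def test_locus_verdict_mixed():
    class R:
        def __init__(self, s, partial=False):
            self.synonymy = s
            self.partial = partial

    assert locus_verdict([R("synonymous"), R("synonymous")]) == "synonymous"
    assert locus_verdict([R("synonymous"), R("nonsynonymous")]) == "mixed"
    assert locus_verdict([R("intergenic")]) == "intergenic"
    assert locus_verdict([R("nonsynonymous"), R("intergenic")]) == "nonsynonymous"
    assert locus_verdict([]) == NA
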