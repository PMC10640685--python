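"""SNP annotation against locally supplied GenBank records.

For each genome listed as annotated, the discovered SNP positions (from
the SNP-discovery pass; nothing is re-searched) are intersected with the
CDS features of the genome's GenBank file.  For a position inside a CDS
the reading-frame-aware codon is reconstructed (respecting strand and
``codon_start``), translated (bacterial/archaeal table 11 by default),
and the alternative alleles observed at the locus are substituted into
the codon to decide synonymous versus nonsynonymous.  Positions in no CDS
are intergenic; a position covered by several CDSs with differing
verdicts is summarized as mixed.

Alleles in the SNP matrix live on the canonical strand of the locus
context; they are mapped back to the genome's forward strand via the
recorded strand flag, and then onto the CDS coding strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq

from .genome_io import GenomeRecord
from .kmer_engine import complement_base
from .snp_discovery import MISSING, SnpLocus, SnpMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotatedGenome",
    "SnpAnnotation",
    "load_annotated_genomes",
    "locate_snp",
    "annotate_snp",
    "annotate_matrix",
    "locus_verdict",
    "write_annotation_reports",
]

GENBANK_EXTENSIONS = (".gbk", ".gb", ".gbff", ".genbank")

NA = "N/A"
PEPTIDE_FLANK = 5  # residues shown on each side of the SNP codon


@dataclass
class CdsFeature:
    """One CDS: genomic extent, strand, frame offset, and product."""

    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: int  # +1 or -1
    codon_start: int  # 1, 2 or 3 (frame offset per GenBank convention)
    product: str
    protein_id: str

    def coding_positions(self) -> List[int]:
        """0-based genomic positions in coding (5'->3' of the CDS) order."""
        if self.strand >= 0:
            positions = list(range(self.start - 1, self.end))
        else:
            positions = list(range(self.end - 1, self.start - 2, -1))
        return positions[self.codon_start - 1 :]


@dataclass
class AnnotatedGenome:
    """A manifest genome together with its parsed GenBank feature table."""

    genome_id: str
    accession: str
    sequences: Dict[str, str]  # contig name -> sequence (uppercase)
    cds: List[CdsFeature] = field(default_factory=list)
    translation_table: int = 11


def _parse_genbank(path, genome_id: str, translation_table: int) -> AnnotatedGenome:
    sequences: Dict[str, str] = {}
    cds: List[CdsFeature] = []
    accession = ""
    for rec in SeqIO.parse(str(path), "genbank"):
        contig = rec.id
        if not accession:
            accession = rec.id
        sequences[contig] = str(rec.seq).upper()
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            loc = feat.location
            strand = loc.strand if loc.strand is not None else 1
            codon_start = int(feat.qualifiers.get("codon_start", ["1"])[0])
            product = feat.qualifiers.get("product", [NA])[0]
            protein_id = feat.qualifiers.get("protein_id", [NA])[0]
            cds.append(
                CdsFeature(
                    contig=contig,
                    start=int(loc.start) + 1,
                    end=int(loc.end),
                    strand=strand,
                    codon_start=codon_start,
                    product=product,
                    protein_id=protein_id,
                )
            )
    if not sequences:
        raise ValueError(f"no GenBank records in {path}")
    return AnnotatedGenome(
        genome_id=genome_id,
        accession=accession,
        sequences=sequences,
        cds=cds,
        translation_table=translation_table,
    )


def _find_genbank_file(genbank_dir: Path, genome_id: str) -> Optional[Path]:
    for ext in GENBANK_EXTENSIONS:
        candidate = genbank_dir / f"{genome_id}{ext}"
        if candidate.exists():
            return candidate
    return None


def load_annotated_genomes(
    list_path,
    genbank_dir,
    genomes: Sequence[GenomeRecord],
    translation_table: int = 11,
) -> List[AnnotatedGenome]:
    """Load GenBank files for the genome IDs listed in ``list_path``.

    Each listed ID must (a) be present in the run's genome set, and
    (b) have a GenBank file ``<genome_id>.gbk`` (or .gb/.gbff/.genbank)
    in ``genbank_dir`` whose sequence matches the FASTA sequence used for
    SNP calling (case-insensitive); contigs are matched by name when the
    names agree, otherwise by order.  Unannotated IDs must be removed
    from the list — they are reported as errors, not skipped.
    """
    genbank_dir = Path(genbank_dir)
    with open(list_path) as fh:
        listed = [line.strip() for line in fh if line.strip()]
    if not listed:
        logger.warning("annotation list %s is empty", list_path)
        return []
    by_id = {g.genome_id: g for g in genomes}
    unknown = [gid for gid in listed if gid not in by_id]
    if unknown:
        raise ValueError(
            f"annotation list names genomes absent from the input set: "
            f"{', '.join(unknown)}"
        )
    missing = [gid for gid in listed if _find_genbank_file(genbank_dir, gid) is None]
    if missing:
        raise FileNotFoundError(
            "no GenBank file found for listed genome(s): "
            + ", ".join(missing)
            + "; remove unannotated genomes from the list"
        )
    out: List[AnnotatedGenome] = []
    for gid in listed:
        ann = _parse_genbank(
            _find_genbank_file(genbank_dir, gid), gid, translation_table
        )
        fasta = by_id[gid]
        fasta_seqs = {name: seq for name, seq in fasta.sequences}
        gb_contigs = list(ann.sequences)
        if set(gb_contigs) == set(fasta_seqs):
            pairs = [(c, c) for c in gb_contigs]
        elif len(gb_contigs) == len(fasta.sequences):
            pairs = list(zip([n for n, _ in fasta.sequences], gb_contigs))
        else:
            raise ValueError(
                f"genome {gid!r}: GenBank contigs do not match FASTA contigs"
            )
        remap: Dict[str, str] = {}
        for fasta_name, gb_name in pairs:
            if fasta_seqs[fasta_name] != ann.sequences[gb_name].upper():
                raise ValueError(
                    f"genome {gid!r}: GenBank sequence of {gb_name!r} "
                    f"differs from the FASTA sequence of {fasta_name!r}"
                )
            remap[gb_name] = fasta_name
        # express everything in FASTA contig names so positions line up
        ann.sequences = {remap[g]: s.upper() for g, s in ann.sequences.items()}
        for feat in ann.cds:
            feat.contig = remap[feat.contig]
        out.append(ann)
    return out


@dataclass
class SnpAnnotation:
    """Annotation of one SNP occurrence (one locus x genome x position)."""

    locus_id: int
    genome_id: str
    accession: str
    contig: str
    position: int
    strand: str
    within_cds: bool
    codon: str = NA
    amino_acid: str = NA
    synonymy: str = "intergenic"
    peptide_context: str = NA
    product: str = NA
    partial: bool = False


def locate_snp(
    locus: SnpLocus, genome_id: str
) -> List[Tuple[str, int, str]]:
    """Positions of a locus in one genome, from the discovery pass."""
    return list(locus.positions.get(genome_id, []))


def _forward_allele(allele: str, strand: str) -> str:
    """Map a canonical-strand allele onto the genome's forward strand."""
    return allele if strand == "+" else complement_base(allele)


def _translate(codon: str, table: int) -> str:
    return str(Seq(codon).translate(table=table))


def annotate_snp(
    locus: SnpLocus,
    genome: AnnotatedGenome,
) -> List[SnpAnnotation]:
    """Annotate every position of one locus in one annotated genome.

    Returns one row per (position, overlapping CDS); positions in no CDS
    yield one intergenic row.  A codon truncated by the CDS end (a
    fractional trailing codon) is flagged partial rather than raised.
    """
    allele = locus.alleles.get(genome.genome_id, MISSING)
    if allele == MISSING:
        return []
    alternatives = [a for a in locus.distinct_alleles() if a != allele]
    rows: List[SnpAnnotation] = []
    for contig, position, strand in locus.positions.get(genome.genome_id, []):
        seq = genome.sequences.get(contig)
        if seq is None:
            logger.warning(
                "contig %r of genome %s has no GenBank sequence; skipping",
                contig,
                genome.genome_id,
            )
            continue
        overlapping = [
            f
            for f in genome.cds
            if f.contig == contig and f.start <= position <= f.end
        ]
        if not overlapping:
            rows.append(
                SnpAnnotation(
                    locus_id=locus.locus_id,
                    genome_id=genome.genome_id,
                    accession=genome.accession,
                    contig=contig,
                    position=position,
                    strand=strand,
                    within_cds=False,
                )
            )
            continue
        fwd_base = _forward_allele(allele, strand)
        for feat in overlapping:
            coding = feat.coding_positions()
            try:
                idx = coding.index(position - 1)
            except ValueError:
                # position trimmed away by codon_start offset
                rows.append(
                    SnpAnnotation(
                        locus_id=locus.locus_id,
                        genome_id=genome.genome_id,
                        accession=genome.accession,
                        contig=contig,
                        position=position,
                        strand=strand,
                        within_cds=True,
                        product=feat.product,
                        synonymy="partial",
                        partial=True,
                    )
                )
                continue
            codon_no = idx // 3
            codon_pos = codon_no * 3
            codon_genomic = coding[codon_pos : codon_pos + 3]
            if len(codon_genomic) < 3:
                rows.append(
                    SnpAnnotation(
                        locus_id=locus.locus_id,
                        genome_id=genome.genome_id,
                        accession=genome.accession,
                        contig=contig,
                        position=position,
                        strand=strand,
                        within_cds=True,
                        product=feat.product,
                        synonymy="partial",
                        partial=True,
                    )
                )
                continue

            def coding_base(gpos: int, base_override: Optional[str] = None) -> str:
                base = base_override if base_override is not None else seq[gpos]
                return base if feat.strand >= 0 else complement_base(base)

            codon = "".join(coding_base(g) for g in codon_genomic)
            offset_in_codon = idx - codon_pos
            # sanity: the reference codon must carry this genome's allele
            expected = coding_base(position - 1, fwd_base)
            codon = (
                codon[:offset_in_codon] + expected + codon[offset_in_codon + 1 :]
            )
            aa = _translate(codon, genome.translation_table)
            verdicts = set()
            for alt in alternatives:
                alt_fwd = _forward_allele(alt, strand)
                alt_cds = coding_base(position - 1, alt_fwd)
                alt_codon = (
                    codon[:offset_in_codon]
                    + alt_cds
                    + codon[offset_in_codon + 1 :]
                )
                alt_aa = _translate(alt_codon, genome.translation_table)
                verdicts.add(
                    "synonymous" if alt_aa == aa else "nonsynonymous"
                )
            synonymy = (
                "nonsynonymous"
                if "nonsynonymous" in verdicts
                else "synonymous"
            )
            first = max(0, codon_no - PEPTIDE_FLANK)
            last = codon_no + PEPTIDE_FLANK + 1
            window_codons = [
                coding[i * 3 : i * 3 + 3]
                for i in range(first, last)
                if len(coding[i * 3 : i * 3 + 3]) == 3
            ]
            peptide = "".join(
                _translate(
                    "".join(coding_base(g) for g in cg),
                    genome.translation_table,
                )
                for cg in window_codons
            )
            rows.append(
                SnpAnnotation(
                    locus_id=locus.locus_id,
                    genome_id=genome.genome_id,
                    accession=genome.accession,
                    contig=contig,
                    position=position,
                    strand=strand,
                    within_cds=True,
                    codon=codon,
                    amino_acid=aa,
                    synonymy=synonymy,
                    peptide_context=peptide,
                    product=feat.product,
                )
            )
    return rows


def locus_verdict(rows: Sequence[SnpAnnotation]) -> str:
    """Summary verdict for one locus across all its annotation rows.

    Coding verdicts dominate intergenic occurrences; a locus with both
    synonymous and nonsynonymous rows (e.g. overlapping CDSs in different
    frames) is mixed.
    """
    verdicts = {r.synonymy for r in rows if not r.partial}
    if not verdicts:
        return "partial" if rows else NA
    coding = verdicts & {"synonymous", "nonsynonymous"}
    if len(coding) == 2:
        return "mixed"
    if len(coding) == 1:
        return coding.pop()
    return "intergenic"


def annotate_matrix(
    matrix: SnpMatrix,
    annotated: Sequence[AnnotatedGenome],
) -> Dict[int, List[SnpAnnotation]]:
    """Annotate every locus against every annotated genome."""
    out: Dict[int, List[SnpAnnotation]] = {}
    for locus in matrix.loci:
        rows: List[SnpAnnotation] = []
        for genome in annotated:
            rows.extend(annotate_snp(locus, genome))
        out[locus.locus_id] = rows
    return out


def write_annotation_reports(
    matrix: SnpMatrix,
    annotations: Dict[int, List[SnpAnnotation]],
    outdir,
) -> Tuple[Path, Path]:
    """Write annotation_summary.tsv and SNPs_all_annotated.tsv.

    The summary has one row per locus (alleles, alternative codons,
    verdict, product); the detailed file has one row per locus x genome x
    position x CDS.  Both are deterministic in locus order.
    """
    outdir = Path(outdir)
    summary_path = outdir / "annotation_summary.tsv"
    detail_path = outdir / "SNPs_all_annotated.tsv"
    with open(summary_path, "w") as fh:
        fh.write("locus_id\tcontext\talleles\tcodons\tsynonymy\tproduct\n")
        for locus in matrix.loci:
            rows = annotations.get(locus.locus_id, [])
            alleles = "/".join(locus.distinct_alleles())
            codons = sorted(
                {r.codon for r in rows if r.codon != NA}
            )
            products = sorted(
                {r.product for r in rows if r.product != NA}
            )
            fh.write(
                f"{locus.locus_id}\t{locus.context}\t{alleles}\t"
                f"{'/'.join(codons) if codons else NA}\t"
                f"{locus_verdict(rows)}\t"
                f"{'; '.join(products) if products else NA}\n"
            )
    with open(detail_path, "w") as fh:
        fh.write(
            "locus_id\tgenome_id\taccession\tcontig\tposition\tstrand\t"
            "allele\tcodon\tamino_acid\tpeptide\tproduct\n"
        )
        for locus in matrix.loci:
            for r in annotations.get(locus.locus_id, []):
                allele = locus.alleles.get(r.genome_id, MISSING)
                fh.write(
                    f"{r.locus_id}\t{r.genome_id}\t{r.accession}\t"
                    f"{r.contig}\t{r.position}\t{r.strand}\t{allele}\t"
                    f"{r.codon}\t{r.amino_acid}\t{r.peptide_context}\t"
                    f"{r.product}\n"
                )
    return summary_path, detail_path
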