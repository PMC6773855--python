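"""Exon-skipping consequence prediction in HGVS c./r./p. terms.

A splice-donor variant (e.g. the +1 G>A that destroys a donor site) causes
the spliceosome to skip the upstream exon. For a transcript model with
known coding-exon boundaries this module computes the transcript-level
deletion (r.), whether the reading frame is preserved, and the
protein-level consequence (p.), with an independent brute-force translation
oracle for cross-checking.

Conventions: c. positions are 1-based from the A of the ATG; the residue
index of cDNA position n is ceil(n/3); r. deletions are reported in cDNA
numbering; p. intervals name the first and last deleted residues
(three-letter amino-acid codes when a CDS sequence is available).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

DONOR_WINDOW_BP = 8  # intronic bases downstream of a donor considered


@dataclass
class Exon:
    """One coding exon: genomic interval (1-based inclusive, on the genome
    strand) and the derived cDNA interval."""

    genomic_start: int
    genomic_end: int
    c_start: int = 0
    c_end: int = 0

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start + 1


@dataclass
class TranscriptModel:
    """Ordered coding exons of one transcript with a bijective
    genomic<->cDNA coordinate map. Exons are given in transcription order
    (for '-' strand transcripts, descending genomic coordinates)."""

    gene_id: str
    strand: str  # '+' or '-'
    exons: list[Exon]
    chrom: str = "."
    cds_sequence: Optional[str] = None  # spliced CDS, multiple of 3 incl. stop

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        c = 1
        for ex in self.exons:
            if ex.genomic_end < ex.genomic_start:
                raise ValueError("exon end before start")
            ex.c_start = c
            ex.c_end = c + ex.length - 1
            c = ex.c_end + 1
        self.cds_length = c - 1
        if self.cds_sequence is not None:
            if len(self.cds_sequence) != self.cds_length:
                raise ValueError(
                    f"CDS sequence length {len(self.cds_sequence)} does not match "
                    f"summed exon length {self.cds_length}"
                )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon(self, index: int) -> Exon:
        """1-based exon index in transcription order."""
        return self.exons[index - 1]

    def genomic_to_cdna(self, pos: int) -> Optional[int]:
        """cDNA coordinate of a genomic position, or None if intronic."""
        for ex in self.exons:
            if ex.genomic_start <= pos <= ex.genomic_end:
                if self.strand == "+":
                    return ex.c_start + (pos - ex.genomic_start)
                return ex.c_start + (ex.genomic_end - pos)
        return None

    def cdna_to_genomic(self, c_pos: int) -> int:
        for ex in self.exons:
            if ex.c_start <= c_pos <= ex.c_end:
                if self.strand == "+":
                    return ex.genomic_start + (c_pos - ex.c_start)
                return ex.genomic_end - (c_pos - ex.c_start)
        raise ValueError(f"c.{c_pos} outside CDS (length {self.cds_length})")

    def boundary_offset(self, pos: int) -> Optional[int]:
        """Signed distance to the nearest intron-exon boundary, in cDNA
        sense: positive = exonic (+1 at the boundary-adjacent exonic base),
        negative = intronic (-1 at the first intronic base). None when the
        position lies outside the transcript span entirely."""
        edges = sorted(
            p for ex in self.exons for p in (ex.genomic_start, ex.genomic_end)
        )
        lo, hi = edges[0], edges[-1]
        if not lo - DONOR_WINDOW_BP * 10 <= pos <= hi + DONOR_WINDOW_BP * 10:
            return None
        exonic = any(
            ex.genomic_start <= pos <= ex.genomic_end for ex in self.exons
        )
        dist = min(abs(pos - e) for e in edges)
        if exonic:
            return dist + 1  # boundary-adjacent exonic base = +1
        return -dist  # first intronic base = -1

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        data = {
            "gene_id": self.gene_id,
            "chrom": self.chrom,
            "strand": self.strand,
            "exons": [[ex.genomic_start, ex.genomic_end] for ex in self.exons],
            "cds_sequence": self.cds_sequence,
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TranscriptModel":
        data = json.loads(Path(path).read_text())
        return cls(
            gene_id=data["gene_id"],
            strand=data["strand"],
            chrom=data.get("chrom", "."),
            exons=[Exon(s, e) for s, e in data["exons"]],
            cds_sequence=data.get("cds_sequence"),
        )

    @classmethod
    def from_gff3(cls, path: str | Path, transcript_id: str) -> "TranscriptModel":
        """Build a model from the CDS features of one transcript in a GFF3
        file (in-memory gffutils database)."""
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        cds = [
            f
            for f in db.features_of_type("CDS")
            if transcript_id in f.attributes.get("Parent", [])
            or f.attributes.get("ID", [""])[0].startswith(transcript_id)
        ]
        if not cds:
            raise ValueError(f"no CDS features for transcript {transcript_id}")
        strand = cds[0].strand
        cds.sort(key=lambda f: f.start, reverse=strand == "-")
        gene = cds[0].attributes.get("gene_id", [transcript_id])[0]
        return cls(
            gene_id=gene,
            strand=strand,
            chrom=cds[0].seqid,
            exons=[Exon(f.start, f.end) for f in cds],
        )


# ---------------------------------------------------------------------------
# Donor-variant localisation
# ---------------------------------------------------------------------------

def locate_donor_variant(
    transcript: TranscriptModel, pos: int
) -> tuple[str, int]:
    """Locate a genomic variant relative to the splice donor sites of a
    transcript: returns the HGVS-style c. notation
    ``c.<last exonic position>+<offset>`` and the 1-based index of the exon
    whose donor is hit. The variant must fall within 8 intronic bp
    downstream of an internal exon's 3' end."""
    for idx, ex in enumerate(transcript.exons, start=1):
        if idx == transcript.n_exons:
            continue  # last exon has no donor
        if transcript.strand == "+":
            offset = pos - ex.genomic_end
        else:
            offset = ex.genomic_start - pos
        if 1 <= offset <= DONOR_WINDOW_BP:
            return f"c.{ex.c_end}+{offset}", idx
    raise ValueError(
        f"position {pos} is outside the {DONOR_WINDOW_BP}-bp donor window of "
        "every internal exon"
    )


# ---------------------------------------------------------------------------
# Skip consequence
# ---------------------------------------------------------------------------

@dataclass
class SkipConsequence:
    """Transcript- and protein-level consequence of skipping one exon."""

    exon_index: int
    r_first: int
    r_last: int
    deleted_nt: int
    in_frame: bool
    start_lost: bool = False
    p_first: Optional[int] = None
    p_last: Optional[int] = None
    deleted_aa: Optional[int] = None
    junction_substitution: bool = False
    hgvs_r: str = ""
    hgvs_p: str = ""

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def exon_skip_consequence(
    transcript: TranscriptModel, exon_index: int
) -> SkipConsequence:
    """Consequence of skipping one internal, fully coding exon.

    The r. deletion is the exon's cDNA interval. The frame is preserved iff
    the exon length is a multiple of 3; for a codon-aligned in-frame skip
    the deleted residues run from ceil(first/3) to last/3 and
    deleted_aa = deleted_nt / 3. An in-frame skip that straddles codons
    removes deleted_nt/3 residues and additionally creates one novel
    junction residue (flagged, not a pure deletion).
    """
    if not 1 <= exon_index <= transcript.n_exons:
        raise ValueError(f"exon index {exon_index} out of range")
    if exon_index == transcript.n_exons:
        raise ValueError("cannot skip the last exon (no donor site)")
    ex = transcript.exon(exon_index)
    first, last = ex.c_start, ex.c_end
    deleted_nt = last - first + 1
    in_frame = deleted_nt % 3 == 0

    cons = SkipConsequence(
        exon_index=exon_index,
        r_first=first,
        r_last=last,
        deleted_nt=deleted_nt,
        in_frame=in_frame,
        hgvs_r=f"r.{first}_{last}del",
    )
    if first <= 3:  # exon contains (part of) the start codon
        cons.start_lost = True
        cons.hgvs_p = "p.Met1?"
        return cons
    if not in_frame:
        cons.hgvs_p = f"p.({math.ceil(first / 3)}fs)"
        return cons

    first_res = math.ceil(first / 3)
    last_res = math.ceil(last / 3)
    codon_aligned = first % 3 == 1  # then last % 3 == 0 automatically
    cons.deleted_aa = deleted_nt // 3
    cons.p_first = first_res
    cons.p_last = last_res
    cons.junction_substitution = not codon_aligned
    if transcript.cds_sequence is not None:
        protein = str(Seq(transcript.cds_sequence).translate())
        name_first = seq3(protein[first_res - 1])
        name_last = seq3(protein[last_res - 1])
    else:
        name_first = name_last = ""
    if codon_aligned:
        cons.hgvs_p = f"p.{name_first}{first_res}_{name_last}{last_res}del"
    else:
        cons.hgvs_p = (
            f"p.{name_first}{first_res}_{name_last}{last_res}delins?"
        )
    return cons


# ---------------------------------------------------------------------------
# Translation oracle
# ---------------------------------------------------------------------------

@dataclass
class ProteinDiff:
    """Residue-level difference between the full and exon-skipped protein."""

    deleted_first: Optional[int]  # 1-based residue index in the full protein
    deleted_last: Optional[int]
    n_deleted: int
    n_substituted: int
    frameshift: bool = False
    stop_gained: bool = False
    inserted: str = ""


def verify_by_translation(
    cds: str, skip_first: int, skip_last: int
) -> ProteinDiff:
    """Brute-force oracle: translate the CDS with and without the skipped
    interval (1-based, inclusive, cDNA coordinates) and align the proteins.

    Independent of the coordinate arithmetic in
    :func:`exon_skip_consequence`; used to cross-check it.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    if not 1 <= skip_first <= skip_last <= len(cds):
        raise ValueError("skip interval outside CDS")
    full = str(Seq(cds).translate())
    skipped_seq = cds[: skip_first - 1] + cds[skip_last:]
    if len(skipped_seq) % 3 != 0:
        return ProteinDiff(None, None, 0, 0, frameshift=True)
    skipped = str(Seq(skipped_seq).translate())

    # strip terminal stops for alignment; note an internal stop in the
    # skipped protein separately
    full_body = full.rstrip("*")
    skipped_body = skipped.rstrip("*")
    stop_gained = "*" in skipped_body

    p = 0
    while p < min(len(full_body), len(skipped_body)) and full_body[p] == skipped_body[p]:
        p += 1
    s = 0
    max_s = min(len(full_body) - p, len(skipped_body) - p)
    while s < max_s and full_body[len(full_body) - 1 - s] == skipped_body[len(skipped_body) - 1 - s]:
        s += 1
    removed = full_body[p : len(full_body) - s]
    inserted = skipped_body[p : len(skipped_body) - s]
    n_deleted = len(removed) - len(inserted)
    if not removed:
        return ProteinDiff(None, None, 0, 0, stop_gained=stop_gained)
    return ProteinDiff(
        deleted_first=p + 1,
        deleted_last=len(full_body) - s,
        n_deleted=n_deleted,
        n_substituted=len(inserted),
        stop_gained=stop_gained,
        inserted=inserted,
    )
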