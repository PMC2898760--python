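"""Virtual NlaIII tag reference.

SAGE-style digital gene expression (DGE) tags are 21 nt sequences anchored at
an NlaIII restriction site (CATG): the enzyme MmeI cuts 17 bp downstream of
CATG, so every sequenced tag is CATG plus the next 17 nt of the transcript's
sense strand.  To map observed tags back to genes we pre-extract, from every
transcript of the reference transcriptome, every possible CATG+17 "virtual
tag", flag the 3'-most one as the *canonical* site (the tag produced by
complete digestion and conventional polyadenylation), and build an inverted
index tag sequence -> genes.  Tags shared by more than one gene are
*ambiguous* and are never used for quantification.

Coordinates are 0-based; ``site_pos`` points at the C of CATG and a tag spans
the half-open interval ``[site_pos, site_pos + 21)``.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import reverse_complement

ANCHOR = "CATG"
TAG_LEN = 21
#: nt retained downstream of the CATG anchor (MmeI cut distance)
TAG_TAIL = TAG_LEN - len(ANCHOR)

_VALID_BASES = frozenset("ACGTN")


class DuplicateGeneIdError(ValueError):
    """Two transcripts in one reference share a gene_id."""


@dataclass(frozen=True)
class Transcript:
    """A reference transcript (uppercase DNA over A/C/G/T/N)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be nonempty")
        if set(self.sequence) - _VALID_BASES:
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise ValueError(
                f"{self.gene_id}: sequence contains invalid characters {bad}; "
                "expected uppercase A/C/G/T/N"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VirtualTag:
    """One CATG+17 tag extracted from a transcript.

    ``is_canonical`` marks the 3'-most usable site of its transcript, the
    only site a completely digested library can produce.
    """

    tag_seq: str
    gene_id: str
    site_pos: int
    is_canonical: bool
    strand: str = "+"


def extract_virtual_tags(
    transcript: Transcript, *, both_strands: bool = False
) -> list[VirtualTag]:
    """Extract every CATG+17 virtual tag from a transcript's sense strand.

    Every CATG occurrence with at least 17 nt downstream yields one tag
    (overlapping occurrences included); truncated tags are never emitted and
    tags containing N are dropped.  The returned tag with the highest
    ``site_pos`` (per strand scanned) carries ``is_canonical=True``.  With
    ``both_strands`` the reverse complement is scanned as well, for de novo
    contigs of unknown orientation; positions are then on the scanned strand.
    """
    tags = _scan_strand(transcript.sequence, transcript.gene_id, "+")
    if both_strands:
        tags += _scan_strand(
            reverse_complement(transcript.sequence), transcript.gene_id, "-"
        )
    return tags


def _scan_strand(seq: str, gene_id: str, strand: str) -> list[VirtualTag]:
    sites: list[int] = []
    start = seq.find(ANCHOR)
    while start != -1:
        if start + TAG_LEN <= len(seq) and "N" not in seq[start : start + TAG_LEN]:
            sites.append(start)
        start = seq.find(ANCHOR, start + 1)
    return [
        VirtualTag(
            tag_seq=seq[pos : pos + TAG_LEN],
            gene_id=gene_id,
            site_pos=pos,
            is_canonical=(pos == sites[-1]),
            strand=strand,
        )
        for pos in sites
    ]


@dataclass
class TagReference:
    """Virtual-tag database over a transcriptome.

    ``index`` maps each distinct tag sequence to the tuple of VirtualTags
    bearing it, sorted by (gene_id, site_pos) so that iteration order never
    depends on input order.
    """

    transcripts: list[Transcript]
    virtual_tags: list[VirtualTag]
    index: dict[str, tuple[VirtualTag, ...]]
    untaggable_genes: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.transcripts)

    @property
    def n_distinct_tags(self) -> int:
        return len(self.index)

    def gene_ids(self, tag_seq: str) -> frozenset[str]:
        return frozenset(vt.gene_id for vt in self.index.get(tag_seq, ()))

    @property
    def n_unambiguous_ref_tags(self) -> int:
        return sum(1 for t in self.index if len(self.gene_ids(t)) == 1)

    @property
    def genes_with_tags(self) -> frozenset[str]:
        return frozenset(vt.gene_id for vt in self.virtual_tags)

    def census(self) -> dict[str, int]:
        """Reference-tag census: the counts a library report is built on."""
        return {
            "n_genes": self.n_genes,
            "n_virtual_tags": len(self.virtual_tags),
            "n_distinct_tags": self.n_distinct_tags,
            "n_unambiguous_ref_tags": self.n_unambiguous_ref_tags,
            "n_genes_with_tags": len(self.genes_with_tags),
            "n_untaggable_genes": len(self.untaggable_genes),
        }


def build_reference(
    transcripts: Iterable[Transcript], *, both_strands: bool = False
) -> TagReference:
    """Build the tag database and inverted index for a transcriptome.

    Raises DuplicateGeneIdError on repeated gene_ids.  Genes without a usable
    CATG site (no CATG at least 21 nt from their 3' end, or shorter than
    21 nt) contribute no tags and are listed as untaggable.
    """
    transcripts = list(transcripts)
    seen: set[str] = set()
    for t in transcripts:
        if t.gene_id in seen:
            raise DuplicateGeneIdError(f"duplicate gene_id {t.gene_id!r}")
        seen.add(t.gene_id)

    all_tags: list[VirtualTag] = []
    untaggable: list[str] = []
    for t in sorted(transcripts, key=lambda t: t.gene_id):
        tags = extract_virtual_tags(t, both_strands=both_strands)
        if tags:
            all_tags.extend(tags)
        else:
            untaggable.append(t.gene_id)

    bucket: dict[str, list[VirtualTag]] = defaultdict(list)
    for vt in all_tags:
        bucket[vt.tag_seq].append(vt)
    index = {
        seq: tuple(sorted(vts, key=lambda v: (v.gene_id, v.strand, v.site_pos)))
        for seq, vts in bucket.items()
    }
    return TagReference(
        transcripts=sorted(transcripts, key=lambda t: t.gene_id),
        virtual_tags=all_tags,
        index=index,
        untaggable_genes=untaggable,
    )


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a (wrapped or single-line) multi-FASTA; gene_id is the first
    whitespace-delimited header token."""
    return [
        Transcript(gene_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.gene_id}\n{t.sequence}\n")


def write_tag_table(ref: TagReference, path: str | Path) -> None:
    """TSV of all virtual tags with their sharing degree."""
    with open(path, "w") as fh:
        fh.write("tag_seq\tgene_id\tsite_pos\tis_canonical\tn_genes_sharing\n")
        for vt in sorted(ref.virtual_tags, key=lambda v: (v.tag_seq, v.gene_id, v.site_pos)):
            n_share = len(ref.gene_ids(vt.tag_seq))
            fh.write(
                f"{vt.tag_seq}\t{vt.gene_id}\t{vt.site_pos}\t"
                f"{int(vt.is_canonical)}\t{n_share}\n"
            )


def write_census(ref: TagReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(ref.census(), fh, indent=2, sort_keys=True)
        fh.write("\n")
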