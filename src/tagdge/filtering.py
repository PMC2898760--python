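"""Raw tag-library cleaning.

A raw DGE library is a multiset of reads.  Before quantification the library
is cleaned with four rules, applied in a fixed order so that the audit trail
is reproducible:

1. ``adaptor_or_empty`` — reads that are adaptor-only, or that do not begin
   with a full CATG+17 tag after adaptor trimming (includes reads whose CATG
   anchor was destroyed by a sequencing error);
2. ``contains_N`` — tags with an undetermined base;
3. ``low_complexity`` — near-homopolymer or pure di-nucleotide-repeat tags;
4. ``copy_number_1`` — after aggregating the surviving reads into distinct
   tags, tags seen exactly once in the whole library are discarded as
   probable sequencing errors.

Occurrence conservation is exact: reads in == reads kept + reads removed,
rule by rule.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .reference import ANCHOR, TAG_LEN

FILTER_RULES = ("adaptor_or_empty", "contains_N", "low_complexity", "copy_number_1")


class AdaptorSequenceError(ValueError):
    """Adaptor sequence contains characters outside A/C/G/T."""


@dataclass
class RawTagLibrary:
    """A sample's raw reads (multiset); reads may be longer than 21 nt."""

    sample_id: str
    reads: Counter = field(default_factory=Counter)

    @property
    def n_raw_total(self) -> int:
        return sum(self.reads.values())

    @property
    def n_raw_distinct(self) -> int:
        return len(self.reads)


@dataclass
class TagLibrary:
    """A cleaned library: distinct CATG+17 tags with counts >= 2 and the
    per-rule removal audit (in read occurrences)."""

    sample_id: str
    counts: dict[str, int]
    filter_log: dict[str, int]

    @property
    def n_clean_total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_clean_distinct(self) -> int:
        return len(self.counts)

    def summary(self) -> dict[str, int]:
        return {
            "n_clean_total": self.n_clean_total,
            "n_clean_distinct": self.n_clean_distinct,
            **{f"removed_{k}": v for k, v in self.filter_log.items()},
        }


def is_low_complexity(tag_seq: str, *, max_mononucleotide: int = 15) -> bool:
    """True if the 17 variable nt are >= ``max_mononucleotide`` copies of one
    base, or a pure di-nucleotide repeat (ACACAC...)."""
    var = tag_seq[len(ANCHOR):]
    if max(Counter(var).values()) >= max_mononucleotide:
        return True
    if var[0] != var[1] and all(var[i] == var[i % 2] for i in range(len(var))):
        return True
    return False


def _extract_tag(read: str, adaptor_seq: str) -> str | None:
    """Trim a leading adaptor if present and return the CATG+17 tag, or None
    if the read cannot yield a full anchored tag."""
    if adaptor_seq and read.startswith(adaptor_seq):
        read = read[len(adaptor_seq):]
    if len(read) < TAG_LEN or not read.startswith(ANCHOR):
        return None
    return read[:TAG_LEN]


def filter_tags(
    raw: RawTagLibrary,
    adaptor_seq: str = "",
    *,
    max_mononucleotide: int = 15,
    drop_singletons: bool = True,
) -> TagLibrary:
    """Clean a raw library; see the module docstring for the rule order.

    ``drop_singletons=False`` keeps copy-number-1 tags (useful when filtering
    an already-aggregated table that excluded them upstream).
    """
    if set(adaptor_seq) - set("ACGT"):
        raise AdaptorSequenceError(f"adaptor contains non-ACGT characters: {adaptor_seq!r}")
    if raw.n_raw_total == 0:
        raise ValueError("raw library is empty")

    log = dict.fromkeys(FILTER_RULES, 0)
    kept: Counter = Counter()
    for read, n in raw.reads.items():
        tag = _extract_tag(read, adaptor_seq)
        if tag is None:
            log["adaptor_or_empty"] += n
        elif "N" in tag:
            log["contains_N"] += n
        elif is_low_complexity(tag, max_mononucleotide=max_mononucleotide):
            log["low_complexity"] += n
        else:
            kept[tag] += n

    if drop_singletons:
        singles = [t for t, n in kept.items() if n == 1]
        log["copy_number_1"] = len(singles)
        for t in singles:
            del kept[t]

    lib = TagLibrary(sample_id=raw.sample_id, counts=dict(kept), filter_log=log)
    assert lib.n_clean_total + sum(log.values()) == raw.n_raw_total
    return lib


def read_fastq(path: str | Path, sample_id: str) -> RawTagLibrary:
    """Load raw reads from a 4-line-record FASTQ (sequence only; qualities
    are not used beyond the N rule applied later)."""
    reads = Counter(str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq"))
    return RawTagLibrary(sample_id=sample_id, reads=reads)


def read_tag_table(path: str | Path, sample_id: str) -> RawTagLibrary:
    """Load a two-column TSV (tag_seq, count); header optional."""
    reads: Counter = Counter()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seq, _, count = line.partition("\t")
            if seq.lower() in {"tag_seq", "tag"}:
                continue
            reads[seq.upper()] += int(count)
    return RawTagLibrary(sample_id=sample_id, reads=reads)


def write_tag_table(lib: TagLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tag_seq\tcount\n")
        for tag in sorted(lib.counts):
            fh.write(f"{tag}\t{lib.counts[tag]}\n")


def write_audit(lib: TagLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"sample_id": lib.sample_id, **lib.summary()}, fh, indent=2)
        fh.write("\n")
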