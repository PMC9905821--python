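"""FASTQ read-quality filters for the two sequencing arms of the study design.

Two rule sets are provided.  ``GBS`` (reduced-representation genotyping
reads) removes a read when it has >= 10% ambiguous bases (N), when more
than 50% of its bases have Phred quality below 5, when any 10-nt stretch
aligns to the sequencing adapter with at most 10% mismatches, or when it
contains a restriction-enzyme recognition site (HaeIII GGCC or EcoRI
GAATTC by default — the double-digest fragments should not contain internal
sites).  ``RESEQ`` (whole-genome resequencing reads) removes a read when it
has more than 10% N or more than 40% low-quality bases (Q <= 20).

Filtering removes a read iff it violates at least one rule; a read that
trips several rules is counted once per rule in the report but removed once.
Filtering is idempotent.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33


class ReadRecord(NamedTuple):
    identifier: str
    sequence: str
    qualities: str  # Phred+33 encoded, same length as sequence


@dataclass(frozen=True)
class QcRuleSet:
    """Thresholds for one filtering mode.

    ``n_fraction_inclusive`` controls the boundary of the N rule: the GBS
    arm removes reads with >= max_n_fraction N, the resequencing arm with
    strictly > max_n_fraction.  ``low_qual_below`` is the exclusive Phred
    bound defining a low-quality base (5 means Q < 5; 21 means Q <= 20).
    """

    mode: str
    max_n_fraction: float = 0.10
    n_fraction_inclusive: bool = True
    low_qual_below: int = 5
    max_low_qual_fraction: float = 0.50
    adapter_sequence: str | None = None
    adapter_match_len: int = 10
    adapter_max_mismatch_fraction: float = 0.10
    forbidden_sites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for f in (self.max_n_fraction, self.max_low_qual_fraction,
                  self.adapter_max_mismatch_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.adapter_sequence is not None and self.adapter_match_len > len(
            self.adapter_sequence
        ):
            raise ValueError("adapter_match_len exceeds adapter length")


# Illumina TruSeq read-1 adapter start; recognition sites per NEB catalogue.
DEFAULT_ADAPTER = "AGATCGGAAGAGC"
HAEIII_SITE = "GGCC"
ECORI_SITE = "GAATTC"
MSEI_SITE = "TTAA"

GBS_RULES = QcRuleSet(
    mode="GBS",
    max_n_fraction=0.10,
    n_fraction_inclusive=True,
    low_qual_below=5,
    max_low_qual_fraction=0.50,
    adapter_sequence=DEFAULT_ADAPTER,
    forbidden_sites=(HAEIII_SITE, ECORI_SITE),
)

RESEQ_RULES = QcRuleSet(
    mode="RESEQ",
    max_n_fraction=0.10,
    n_fraction_inclusive=False,
    low_qual_below=21,  # Q <= 20 counts as low quality
    max_low_qual_fraction=0.40,
    adapter_sequence=None,
    forbidden_sites=(),
)


@dataclass
class FilterReport:
    total: int = 0
    kept: int = 0
    removed: int = 0
    by_rule: dict[str, int] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = [
            {"rule": "total", "count": self.total},
            {"rule": "kept", "count": self.kept},
            {"rule": "removed", "count": self.removed},
        ]
        rows += [{"rule": k, "count": v} for k, v in sorted(self.by_rule.items())]
        return rows


def _adapter_hit(seq: str, rules: QcRuleSet) -> bool:
    adapter = rules.adapter_sequence
    if not adapter:
        return False
    k = rules.adapter_match_len
    max_mm = int(rules.adapter_max_mismatch_fraction * k)
    if len(seq) < k:
        return False
    adapter_windows = [adapter[j : j + k] for j in range(len(adapter) - k + 1)]
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        for aw in adapter_windows:
            mm = sum(a != b for a, b in zip(window, aw))
            if mm <= max_mm:
                return True
    return False


def failed_rules(read: ReadRecord, rules: QcRuleSet) -> list[str]:
    """Names of every rule the read violates (empty when it passes)."""
    seq = read.sequence.upper()
    n = len(seq)
    if n == 0:
        return ["empty"]
    fails = []
    n_frac = seq.count("N") / n
    if (n_frac >= rules.max_n_fraction) if rules.n_fraction_inclusive else (
        n_frac > rules.max_n_fraction
    ):
        fails.append("n_fraction")
    low = sum(1 for q in read.qualities if ord(q) - PHRED_OFFSET < rules.low_qual_below)
    if low / n > rules.max_low_qual_fraction:
        fails.append("low_quality")
    if _adapter_hit(seq, rules):
        fails.append("adapter")
    if any(site in seq for site in rules.forbidden_sites):
        fails.append("restriction_site")
    return fails


def filter_reads(
    reads: Iterable[ReadRecord], rules: QcRuleSet
) -> tuple[list[ReadRecord], FilterReport]:
    """Apply a rule set; returns the surviving reads and a removal report."""
    report = FilterReport()
    kept: list[ReadRecord] = []
    for read in reads:
        report.total += 1
        fails = failed_rules(read, rules)
        if fails:
            report.removed += 1
            for rule in fails:
                report.by_rule[rule] = report.by_rule.get(rule, 0) + 1
        else:
            kept.append(read)
    report.kept = len(kept)
    return kept, report


def filter_read_pairs(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]], rules: QcRuleSet
) -> tuple[list[tuple[ReadRecord, ReadRecord]], FilterReport]:
    """Paired-end mode: a pair is dropped when either mate fails any rule."""
    report = FilterReport()
    kept = []
    for r1, r2 in pairs:
        report.total += 1
        fails = sorted(set(failed_rules(r1, rules)) | set(failed_rules(r2, rules)))
        if fails:
            report.removed += 1
            for rule in fails:
                report.by_rule[rule] = report.by_rule.get(rule, 0) + 1
        else:
            kept.append((r1, r2))
    report.kept = len(kept)
    return kept, report


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate a (optionally gzipped) FASTQ file; malformed records raise
    with the approximate line number."""
    with _open_text(path) as fh:
        n_records = 0
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                if len(seq) != len(qual):
                    raise ValueError("sequence/quality length mismatch")
                yield ReadRecord(title.split()[0], seq, qual)
                n_records += 1
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ near line {n_records * 4 + 1} of {path}: {exc}"
            ) from exc


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        for r in reads:
            fh.write(f"@{r.identifier}\n{r.sequence}\n+\n{r.qualities}\n")
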