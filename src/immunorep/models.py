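"""Core domain types shared across the package.

The unit of observation is an assembled receptor-chain rearrangement with a
CDR3 junction; samples aggregate rearrangements together with the size of the
RNA-seq library they were extracted from (needed for per-kiloread
normalisation downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

#: The seven receptor chain loci handled throughout the package.
LOCI: tuple[str, ...] = ("IGH", "IGK", "IGL", "TRA", "TRB", "TRD", "TRG")

BCR_LOCI: frozenset[str] = frozenset({"IGH", "IGK", "IGL"})
TCR_LOCI: frozenset[str] = frozenset({"TRA", "TRB", "TRD", "TRG"})


@dataclass
class RearrangementRecord:
    """One assembled receptor-chain observation (one contig / CDR3).

    ``out_of_frame`` is set automatically when the nucleotide junction length
    is inconsistent with the amino-acid junction (len(nt) != 3 * len(aa)).
    """

    sample_id: str
    locus: str
    v_call: str
    j_call: str
    cdr3_nt: str
    cdr3_aa: str
    read_count: int
    is_complete: bool = True
    sequence_id: str = ""
    out_of_frame: bool = False

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise ValueError(
                f"locus {self.locus!r} is not one of {', '.join(LOCI)}"
            )
        if self.read_count < 0:
            raise ValueError(f"read_count must be >= 0, got {self.read_count}")
        if self.cdr3_nt and self.cdr3_aa:
            if len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
                self.out_of_frame = True

    @property
    def is_bcr(self) -> bool:
        return self.locus in BCR_LOCI

    @property
    def is_tcr(self) -> bool:
        return self.locus in TCR_LOCI


@dataclass
class SampleRepertoire:
    """All rearrangement records of one sample plus its library size."""

    sample_id: str
    records: list[RearrangementRecord] = field(default_factory=list)
    library_reads: int = 1

    def __post_init__(self) -> None:
        if self.library_reads <= 0:
            raise ValueError("library_reads must be positive")
        for rec in self.records:
            if rec.sample_id != self.sample_id:
                raise ValueError(
                    f"record sample_id {rec.sample_id!r} does not match "
                    f"repertoire sample_id {self.sample_id!r}"
                )
        total = sum(r.read_count for r in self.records)
        if self.library_reads < total:
            raise ValueError(
                f"library_reads ({self.library_reads}) smaller than total "
                f"receptor read count ({total})"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[RearrangementRecord]:
        return iter(self.records)

    def subset(self, records: Iterable[RearrangementRecord]) -> "SampleRepertoire":
        """A new repertoire over ``records``, keeping sample id and library size."""
        return SampleRepertoire(
            sample_id=self.sample_id,
            records=list(records),
            library_reads=self.library_reads,
        )


@dataclass
class ClinicalRecord:
    """Clinical metadata for one case."""

    sample_id: str
    phenotype: str  # "LSP" or "HSP"
    stage: str | None  # "I".."IV" or None
    os_days: float
    event: int  # 1 = death, 0 = censored

    def __post_init__(self) -> None:
        if self.phenotype not in ("LSP", "HSP"):
            raise ValueError(f"phenotype must be LSP or HSP, got {self.phenotype!r}")
        if self.stage is not None and self.stage not in ("I", "II", "III", "IV"):
            raise ValueError(f"stage must be I..IV or missing, got {self.stage!r}")
        if self.os_days < 0:
            raise ValueError("os_days must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def clone_record(rec: RearrangementRecord, **changes) -> RearrangementRecord:
    """Copy a record with field overrides (dataclasses.replace wrapper)."""
    return replace(rec, **changes)
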