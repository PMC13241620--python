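"""Clone identification.

A clone is an equivalence class of rearrangements sharing V gene, J gene and
CDR3 nucleotide length, clustered by single-linkage on pairwise CDR3
nucleotide identity at a chain-class-specific threshold (BCR 0.90, TCR 0.95,
both inclusive). Within an equal-length group, identity is Hamming identity;
'N' bases never count as matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .models import BCR_LOCI, RearrangementRecord, SampleRepertoire

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClonotypingConfig:
    bcr_identity_threshold: float = 0.90
    tcr_identity_threshold: float = 0.95
    gene_match_level: str = "gene"  # "gene" or "allele"
    linkage: str = "single"

    def __post_init__(self) -> None:
        for name in ("bcr_identity_threshold", "tcr_identity_threshold"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.gene_match_level not in ("gene", "allele"):
            raise ValueError("gene_match_level must be 'gene' or 'allele'")
        if self.linkage != "single":
            raise ValueError("only single linkage is supported")

    def threshold_for(self, locus: str) -> float:
        return (
            self.bcr_identity_threshold
            if locus in BCR_LOCI
            else self.tcr_identity_threshold
        )


@dataclass
class Clone:
    clone_id: str
    sample_id: str
    locus: str
    v_gene: str
    j_gene: str
    cdr3_length: int
    members: list[RearrangementRecord]
    representative_cdr3: str = ""
    total_reads: int = 0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a clone must have at least one member")
        self.total_reads = sum(m.read_count for m in self.members)
        self.representative_cdr3 = min(m.cdr3_nt for m in self.members)


@dataclass
class CloneSet:
    sample_id: str
    clones: list[Clone] = field(default_factory=list)
    n_unassigned: int = 0

    @property
    def n_unique(self) -> int:
        return len(self.clones)

    @property
    def n_reads(self) -> int:
        return sum(c.total_reads for c in self.clones)


def gene_name(call: str, level: str = "gene") -> str:
    """Normalise a V/J call; at gene level the allele suffix (``*01``) is stripped."""
    call = call.strip()
    if level == "gene":
        return call.split("*", 1)[0]
    return call


def cdr3_identity(a: str, b: str) -> float:
    """Fraction of positions with equal, non-'N' bases; requires equal lengths."""
    if len(a) != len(b) or not a:
        raise ValueError(
            f"cdr3_identity requires equal non-zero lengths, got {len(a)} and {len(b)}"
        )
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "N")
    return matches / len(a)


def _sort_key(rec: RearrangementRecord) -> tuple[str, str]:
    return (rec.cdr3_nt, rec.sequence_id)


def partition_group(
    records: list[RearrangementRecord],
    threshold: float,
    sample_id: str | None = None,
    gene_match_level: str = "gene",
) -> list[Clone]:
    """Single-linkage connected components within one (locus, V, J, length) group.

    An edge joins records i, j iff cdr3_identity(i, j) >= threshold. Output
    is deterministic and independent of input order: members are sorted
    lexicographically by (cdr3_nt, sequence_id) and components by their
    smallest member.
    """
    if not records:
        return []
    first = records[0]
    key = (
        first.locus,
        gene_name(first.v_call, gene_match_level),
        gene_name(first.j_call, gene_match_level),
        len(first.cdr3_nt),
    )
    for rec in records[1:]:
        rec_key = (
            rec.locus,
            gene_name(rec.v_call, gene_match_level),
            gene_name(rec.j_call, gene_match_level),
            len(rec.cdr3_nt),
        )
        if rec_key != key:
            raise ValueError(
                f"record {rec.sequence_id!r} with key {rec_key} does not share "
                f"the group key {key}"
            )

    ordered = sorted(records, key=_sort_key)
    parent = list(range(len(ordered)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            if cdr3_identity(ordered[i].cdr3_nt, ordered[j].cdr3_nt) >= threshold:
                union(i, j)

    components: dict[int, list[RearrangementRecord]] = {}
    for i, rec in enumerate(ordered):
        components.setdefault(find(i), []).append(rec)

    locus, v_gene, j_gene, length = key
    sid = sample_id if sample_id is not None else first.sample_id
    clones = []
    for idx, root in enumerate(sorted(components)):
        members = components[root]  # already in sorted order
        clones.append(
            Clone(
                clone_id=f"{sid}|{locus}|{v_gene}|{j_gene}|{length}|{idx:03d}",
                sample_id=sid,
                locus=locus,
                v_gene=v_gene,
                j_gene=j_gene,
                cdr3_length=length,
                members=members,
            )
        )
    return clones


def assign_clones(rep: SampleRepertoire, cfg: ClonotypingConfig | None = None) -> CloneSet:
    """Group a productive-filtered repertoire into clones.

    Records are keyed by (locus, V gene, J gene, CDR3 length) at the
    configured gene-match level, then each group is clustered at the
    BCR/TCR threshold for its chain class. Records lacking a V or J call
    (or a CDR3) are excluded and counted in an "unassigned" bucket.
    """
    cfg = cfg or ClonotypingConfig()
    groups: dict[tuple[str, str, str, int], list[RearrangementRecord]] = {}
    n_unassigned = 0
    for rec in rep:
        if not rec.v_call or not rec.j_call or not rec.cdr3_nt:
            n_unassigned += 1
            continue
        key = (
            rec.locus,
            gene_name(rec.v_call, cfg.gene_match_level),
            gene_name(rec.j_call, cfg.gene_match_level),
            len(rec.cdr3_nt),
        )
        groups.setdefault(key, []).append(rec)
    if n_unassigned:
        logger.warning(
            "%s: %d records without V/J call or CDR3 left unassigned",
            rep.sample_id, n_unassigned,
        )

    clones: list[Clone] = []
    for key in sorted(groups):
        locus = key[0]
        clones.extend(
            partition_group(
                groups[key],
                cfg.threshold_for(locus),
                sample_id=rep.sample_id,
                gene_match_level=cfg.gene_match_level,
            )
        )
    return CloneSet(sample_id=rep.sample_id, clones=clones, n_unassigned=n_unassigned)


def clone_table(clone_set: CloneSet):
    """Clone summary as a pandas DataFrame (one row per clone)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "locus": c.locus,
                "clone_id": c.clone_id,
                "v_gene": c.v_gene,
                "j_gene": c.j_gene,
                "cdr3_length": c.cdr3_length,
                "representative_cdr3": c.representative_cdr3,
                "n_members": len(c.members),
                "total_reads": c.total_reads,
            }
            for c in clone_set.clones
        ],
        columns=[
            "sample_id", "locus", "clone_id", "v_gene", "j_gene",
            "cdr3_length", "representative_cdr3", "n_members", "total_reads",
        ],
    )
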