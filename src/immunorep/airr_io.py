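"""Reading and writing repertoire tables.

Two dialects are supported: the AIRR Rearrangement TSV standard (MiAIRR
column names) and the simple-report TSV emitted by bulk RNA-seq repertoire
extraction tools (columns ``count, frequency, CDR3nt, CDR3aa, V, D, J, C``).
A productivity filter retains in-frame, stop-free, complete-CDR3 records.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .models import LOCI, RearrangementRecord, SampleRepertoire

logger = logging.getLogger(__name__)

#: Maximum tolerated fraction of 'N' bases in a CDR3 at load time.
MAX_N_FRACTION = 0.10

#: Count-column precedence in AIRR tables (strongest evidence first).
_COUNT_COLUMNS = ("consensus_count", "duplicate_count", "count")

_TRUST4_COLUMNS = ("count", "frequency", "CDR3nt", "CDR3aa", "V", "D", "J", "C")

_TRUE_STRINGS = {"t", "true", "1", "yes", "y"}

_AIRR_OUTPUT_COLUMNS = [
    "sequence_id",
    "locus",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "productive",
    "vj_in_frame",
    "complete_vdj",
    "consensus_count",
]


class AirrFormatError(ValueError):
    """A repertoire table does not conform to the expected dialect."""


def infer_locus(*calls: str) -> str | None:
    """Infer the chain locus from gene-call prefixes (e.g. ``TRBV7-2*01`` -> TRB)."""
    for call in calls:
        prefix = (call or "")[:3].upper()
        if prefix in LOCI:
            return prefix
    return None


def translate_cdr3(cdr3_nt: str) -> str:
    """Translate a junction in frame 0; ambiguous codons become 'X'."""
    usable = cdr3_nt[: len(cdr3_nt) - len(cdr3_nt) % 3]
    if not usable:
        return ""
    return str(Seq(usable).translate())


def _aa_consistent(observed: str, translated: str) -> bool:
    # 'X' (from 'N' bases or partial assembly) matches anything.
    if len(observed) != len(translated):
        return False
    return all(a == b or "X" in (a, b) for a, b in zip(observed, translated))


def _looks_complete(cdr3_aa: str) -> bool:
    # Canonical junction anchors: cysteine start, phenylalanine/tryptophan end.
    return len(cdr3_aa) >= 3 and cdr3_aa[0] == "C" and cdr3_aa[-1] in "FW"


def _parse_bool(value: str) -> bool:
    return value.strip().lower() in _TRUE_STRINGS


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _n_fraction(cdr3_nt: str) -> float:
    if not cdr3_nt:
        return 0.0
    return cdr3_nt.count("N") / len(cdr3_nt)


def read_airr_table(
    path: str | Path, sample_id: str, library_reads: int
) -> SampleRepertoire:
    """Load an AIRR Rearrangement TSV into a :class:`SampleRepertoire`.

    Column requirements: ``v_call``, ``j_call``, a junction column
    (``junction`` or ``cdr3``) and an amino-acid junction column
    (``junction_aa`` or ``cdr3_aa``). Locus is taken from a ``locus`` column
    when present, otherwise inferred from the V/J call prefix. Read support
    is taken from the first available of ``consensus_count``,
    ``duplicate_count``, ``count``; absent => 1 per row.
    """
    df = _read_tsv(path)
    if df.empty and len(df.columns) == 0:
        return SampleRepertoire(sample_id, [], library_reads)

    for col in ("v_call", "j_call"):
        if col not in df.columns:
            raise AirrFormatError(f"missing mandatory column: {col}")
    nt_col = next((c for c in ("junction", "cdr3") if c in df.columns), None)
    if nt_col is None:
        raise AirrFormatError("missing mandatory column: junction (or cdr3)")
    aa_col = next((c for c in ("junction_aa", "cdr3_aa") if c in df.columns), None)
    if aa_col is None:
        raise AirrFormatError("missing mandatory column: junction_aa (or cdr3_aa)")
    count_col = next((c for c in _COUNT_COLUMNS if c in df.columns), None)

    records: list[RearrangementRecord] = []
    n_dropped_n = 0
    n_no_locus = 0
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        cdr3_nt = row[nt_col].strip().upper()
        cdr3_aa = row[aa_col].strip()
        if _n_fraction(cdr3_nt) > MAX_N_FRACTION:
            n_dropped_n += 1
            continue
        locus = row.get("locus", "").strip().upper() or None
        if locus not in LOCI:
            locus = infer_locus(row["v_call"], row["j_call"])
        if locus is None:
            n_no_locus += 1
            continue
        count = 1
        if count_col and row[count_col].strip():
            count = int(float(row[count_col]))
        if "complete_vdj" in df.columns and row["complete_vdj"].strip():
            is_complete = _parse_bool(row["complete_vdj"])
        elif "is_complete" in df.columns and row["is_complete"].strip():
            is_complete = _parse_bool(row["is_complete"])
        else:
            is_complete = _looks_complete(cdr3_aa)
        out_of_frame = False
        if "vj_in_frame" in df.columns and row["vj_in_frame"].strip():
            out_of_frame = not _parse_bool(row["vj_in_frame"])
        records.append(
            RearrangementRecord(
                sample_id=sample_id,
                locus=locus,
                v_call=row["v_call"].strip(),
                j_call=row["j_call"].strip(),
                cdr3_nt=cdr3_nt,
                cdr3_aa=cdr3_aa,
                read_count=count,
                is_complete=is_complete,
                sequence_id=row.get("sequence_id", "").strip() or f"{sample_id}-{i}",
                out_of_frame=out_of_frame,
            )
        )
    if n_dropped_n:
        logger.warning(
            "%s: dropped %d records with >%.0f%% 'N' in CDR3",
            sample_id, n_dropped_n, 100 * MAX_N_FRACTION,
        )
    if n_no_locus:
        logger.warning("%s: dropped %d records with underivable locus", sample_id, n_no_locus)
    return SampleRepertoire(sample_id, records, library_reads)


def read_trust4_report(
    path: str | Path, sample_id: str, library_reads: int
) -> SampleRepertoire:
    """Load a TRUST4-style simple report (count/frequency/CDR3nt/CDR3aa/V/D/J/C).

    ``.`` denotes a missing field; a CDR3aa of ``out_of_frame`` loads the
    record with its out-of-frame flag set.
    """
    df = _read_tsv(path)
    if df.empty and len(df.columns) == 0:
        return SampleRepertoire(sample_id, [], library_reads)
    # The tool prefixes the header with '#'.
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [c for c in _TRUST4_COLUMNS if c not in df.columns]
    if missing:
        raise AirrFormatError(
            f"unrecognized simple-report header; missing columns: {', '.join(missing)}"
        )

    def _field(value: str) -> str:
        value = value.strip()
        return "" if value == "." else value

    records: list[RearrangementRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        cdr3_aa = _field(row["CDR3aa"])
        out_of_frame = cdr3_aa == "out_of_frame"
        if out_of_frame:
            cdr3_aa = ""
        cdr3_nt = _field(row["CDR3nt"]).upper()
        if _n_fraction(cdr3_nt) > MAX_N_FRACTION:
            logger.warning("%s: dropped record %d with high-N CDR3", sample_id, i)
            continue
        v_call, j_call = _field(row["V"]), _field(row["J"])
        locus = infer_locus(v_call, j_call, _field(row["C"]))
        if locus is None:
            logger.warning("%s: dropped record %d with underivable locus", sample_id, i)
            continue
        records.append(
            RearrangementRecord(
                sample_id=sample_id,
                locus=locus,
                v_call=v_call,
                j_call=j_call,
                cdr3_nt=cdr3_nt,
                cdr3_aa=cdr3_aa,
                read_count=int(float(row["count"])),
                is_complete=_looks_complete(cdr3_aa),
                sequence_id=f"{sample_id}-{i}",
                out_of_frame=out_of_frame,
            )
        )
    return SampleRepertoire(sample_id, records, library_reads)


def is_productive(rec: RearrangementRecord) -> bool:
    """In-frame, stop-free, complete-CDR3 test for one record."""
    if not rec.cdr3_nt or not rec.is_complete or rec.out_of_frame:
        return False
    if len(rec.cdr3_nt) % 3 != 0:
        return False
    translated = translate_cdr3(rec.cdr3_nt)
    if "*" in translated:
        return False
    if rec.cdr3_aa:
        if "*" in rec.cdr3_aa:
            return False
        if not _aa_consistent(rec.cdr3_aa, translated):
            return False
    return True


def filter_productive(rep: SampleRepertoire) -> SampleRepertoire:
    """Retain productive records (order preserved); idempotent."""
    return rep.subset(r for r in rep if is_productive(r))


def write_rearrangements(rep: SampleRepertoire, path: str | Path) -> None:
    """Write an AIRR-standard TSV that round-trips through :func:`read_airr_table`."""
    rows = []
    for rec in rep:
        rows.append(
            {
                "sequence_id": rec.sequence_id,
                "locus": rec.locus,
                "v_call": rec.v_call,
                "d_call": "",
                "j_call": rec.j_call,
                "junction": rec.cdr3_nt,
                "junction_aa": rec.cdr3_aa,
                "productive": "T" if is_productive(rec) else "F",
                "vj_in_frame": "F" if rec.out_of_frame else "T",
                "complete_vdj": "T" if rec.is_complete else "F",
                "consensus_count": rec.read_count,
            }
        )
    df = pd.DataFrame(rows, columns=_AIRR_OUTPUT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Load the clinical metadata TSV (sample_id, phenotype, stage, vital_status, os_days)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = ["sample_id", "phenotype", "stage", "vital_status", "os_days"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AirrFormatError(f"clinical table missing columns: {', '.join(missing)}")
    bad = set(df["phenotype"]) - {"LSP", "HSP"}
    if bad:
        raise AirrFormatError(f"unknown phenotype labels: {sorted(bad)}")
    return df
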