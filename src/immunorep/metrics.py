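"""Per-(sample, chain) repertoire metrics: abundance, CPK, entropy, clonality.

Clone frequencies are read-count weighted. Entropy is reported in nats by
default (clonality is log-base invariant). Undefined quantities — entropy of
an empty locus, clonality with fewer than two clones — are NaN and written
out as "NA"; they must propagate to downstream statistics as missing values,
never as zero.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import LOCI
from .clonotyping import CloneSet

#: CPK normalisation modes: unique clones per thousand library reads
#: (primary, matches the acronym) or per million library reads.
CPK_MODES = ("per_kiloread", "per_million")


def shannon_entropy(clone_read_counts: Sequence[int], base: str = "nats") -> float:
    """Shannon index over read-count-weighted clone frequencies.

    Returns NaN (undefined) for an empty list; raises on non-positive counts.
    ``base`` is "nats" (default) or "bits".
    """
    counts = np.asarray(list(clone_read_counts), dtype=float)
    if counts.size == 0:
        return float("nan")
    if np.any(counts <= 0):
        raise ValueError("all clone read counts must be positive")
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    h = max(h, 0.0)
    if base == "bits":
        return h / math.log(2)
    if base != "nats":
        raise ValueError(f"unknown entropy base {base!r}")
    return h


def clonality(clone_read_counts: Sequence[int]) -> float:
    """1 - H / ln(R); undefined (NaN) for fewer than two clones."""
    counts = list(clone_read_counts)
    if len(counts) < 2:
        return float("nan")
    h = shannon_entropy(counts, base="nats")
    c = 1.0 - h / math.log(len(counts))
    return min(max(c, 0.0), 1.0)


def cpk(n_clones: int, library_reads: int, mode: str = "per_kiloread") -> float:
    """Unique clones normalised by library size (per kiloread or per million)."""
    if library_reads <= 0:
        raise ValueError("library_reads must be positive")
    if n_clones < 0:
        raise ValueError("n_clones must be non-negative")
    if mode == "per_kiloread":
        return 1000.0 * n_clones / library_reads
    if mode == "per_million":
        return 1e6 * n_clones / library_reads
    raise ValueError(f"unknown CPK mode {mode!r}; expected one of {CPK_MODES}")


def compute_all(
    clones: CloneSet,
    library_reads: int,
    cpk_mode: str = "per_kiloread",
    entropy_base: str = "nats",
) -> pd.DataFrame:
    """One metrics row per locus (all seven, zero/NA rows for absent loci)."""
    by_locus: dict[str, list[int]] = {locus: [] for locus in LOCI}
    for clone in clones.clones:
        by_locus[clone.locus].append(clone.total_reads)

    rows = []
    for locus in LOCI:
        counts = by_locus[locus]
        n = len(counts)
        rows.append(
            {
                "sample_id": clones.sample_id,
                "locus": locus,
                "abundance": int(sum(counts)),
                "n_clones": n,
                "cpk": cpk(n, library_reads, mode=cpk_mode),
                "entropy": shannon_entropy(counts, base=entropy_base),
                "clonality": clonality(counts),
            }
        )
    return pd.DataFrame(rows)


def metrics_table(
    clone_sets: Iterable[CloneSet],
    library_reads: dict[str, int],
    cpk_mode: str = "per_kiloread",
    entropy_base: str = "nats",
) -> pd.DataFrame:
    """Concatenated per-sample metrics for a cohort."""
    frames = [
        compute_all(cs, library_reads[cs.sample_id], cpk_mode, entropy_base)
        for cs in clone_sets
    ]
    if not frames:
        return pd.DataFrame(
            columns=["sample_id", "locus", "abundance", "n_clones", "cpk", "entropy", "clonality"]
        )
    return pd.concat(frames, ignore_index=True)


def write_metrics(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
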