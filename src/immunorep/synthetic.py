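"""Synthetic cohort generator.

Produces full cohorts — per-sample receptor repertoires, clinical metadata,
and marker-gene expression — with the statistical structure the analysis
pipeline assumes: the low-steroid phenotype (LSP) gets richer, more even
repertoires with higher read abundance; the high-steroid phenotype (HSP)
gets sparser, more skewed ones; marker expression is positively coupled to
chain abundance (more strongly in LSP); and survival times carry a strong
protective LSP effect (default hazard ratio 0.1) plus a stage effect.

Clone-size distributions follow a Zipf law with a phenotype-specific
exponent, which monotonically controls the expected entropy gap between the
groups. Generated sequences are guaranteed to be recovered as the designed
clones by the clonotyping stage: within-clone variants stay at or above the
identity threshold relative to an always-emitted founder sequence, and
founders of distinct clones in the same (V, J, length) group are kept far
enough apart that no cross-clone linkage is possible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .airr_io import translate_cdr3, write_rearrangements
from .models import BCR_LOCI, LOCI, RearrangementRecord, SampleRepertoire

# ---------------------------------------------------------------------------
# Parameters

_DEFAULT_READ_MEAN_LSP = {
    "IGH": 1500.0, "IGK": 1200.0, "IGL": 900.0,
    "TRA": 15.0, "TRB": 20.0, "TRD": 1.5, "TRG": 4.0,
}
_DEFAULT_READ_MEAN_HSP = {
    "IGH": 500.0, "IGK": 400.0, "IGL": 300.0,
    "TRA": 1.5, "TRB": 2.0, "TRD": 0.15, "TRG": 0.4,
}

#: Tumor-stage sampling proportions (stage I..IV).
_STAGE_PROBS = {"I": 9 / 76, "II": 37 / 76, "III": 16 / 76, "IV": 14 / 76}

B_CELL_MARKERS = ["CD19", "MS4A1", "CD27", "CD38", "CD40", "CD79A"]
T_CELL_MARKERS = ["CD3D", "CD3E", "CD8A", "CD8B", "IFNG", "TBX21", "STAT4"]


@dataclass
class SimulationParams:
    n_lsp: int = 31
    n_hsp: int = 47
    seed: int = 0
    # read abundance (negative-binomial mean per locus, by phenotype)
    read_mean_lsp: dict = field(default_factory=lambda: dict(_DEFAULT_READ_MEAN_LSP))
    read_mean_hsp: dict = field(default_factory=lambda: dict(_DEFAULT_READ_MEAN_HSP))
    read_dispersion: float = 2.0  # NB shape; smaller = more overdispersed
    # clone structure
    zipf_lsp: float = 0.6   # clone-size concentration (smaller = more even)
    zipf_hsp: float = 1.6
    richness_lsp: float = 1.0  # scales clone count ~ richness * reads**0.7
    richness_hsp: float = 0.7
    mutation_rate: float = 0.01  # per-base within-clone variant mutation rate
    variants_per_clone: float = 0.5  # Poisson mean of extra variants
    bcr_identity_threshold: float = 0.90
    tcr_identity_threshold: float = 0.95
    corruption_fraction: float = 0.0  # fraction of unproductive/incomplete records
    # expression coupling
    coupling_lsp: float = 0.9
    coupling_hsp: float = 0.3
    expression_noise: float = 0.6
    expression_base: float = 3.0
    # survival
    baseline_hazard: float = 8e-4  # per day, HSP stage-II reference
    phenotype_log_hr: float = math.log(0.1)  # LSP vs HSP
    stage_log_hr: float = 0.4  # per ordinal stage step (centred on II)
    censor_rate: float = 5e-5  # independent exponential censoring
    admin_censor_days: float = 3650.0
    # library size (lognormal, phenotype-independent)
    library_log_mean: float = math.log(2e6)
    library_log_sigma: float = 0.5

    def read_mean(self, phenotype: str, locus: str) -> float:
        means = self.read_mean_lsp if phenotype == "LSP" else self.read_mean_hsp
        return means[locus]

    def zipf(self, phenotype: str) -> float:
        return self.zipf_lsp if phenotype == "LSP" else self.zipf_hsp

    def richness(self, phenotype: str) -> float:
        return self.richness_lsp if phenotype == "LSP" else self.richness_hsp

    def threshold(self, locus: str) -> float:
        return (
            self.bcr_identity_threshold
            if locus in BCR_LOCI
            else self.tcr_identity_threshold
        )


def paper_like_params(seed: int = 0, **overrides) -> SimulationParams:
    """Default phenotype-contrasted settings."""
    return SimulationParams(seed=seed, **overrides)


def null_params(seed: int = 0, **overrides) -> SimulationParams:
    """Null settings: no phenotype effect anywhere (for calibration tests)."""
    params = SimulationParams(seed=seed, **overrides)
    params.read_mean_hsp = dict(params.read_mean_lsp)
    params.zipf_hsp = params.zipf_lsp
    params.richness_hsp = params.richness_lsp
    params.coupling_hsp = params.coupling_lsp
    params.phenotype_log_hr = 0.0
    params.stage_log_hr = 0.0
    return params


@dataclass
class SimulatedCohort:
    repertoires: dict  # sample_id -> SampleRepertoire
    clinical: pd.DataFrame
    expression: pd.DataFrame  # genes x samples, log2(TPM+1)-like scale
    truth: dict


# ---------------------------------------------------------------------------
# Sequence machinery

_V_GENES = {
    "IGH": ["IGHV1-2", "IGHV1-69", "IGHV3-23", "IGHV4-34", "IGHV5-51"],
    "IGK": ["IGKV1-5", "IGKV2-28", "IGKV3-20", "IGKV4-1"],
    "IGL": ["IGLV1-40", "IGLV2-14", "IGLV3-1"],
    "TRA": ["TRAV1-2", "TRAV8-4", "TRAV12-1", "TRAV29"],
    "TRB": ["TRBV5-1", "TRBV7-2", "TRBV19", "TRBV20-1"],
    "TRD": ["TRDV1", "TRDV2"],
    "TRG": ["TRGV3", "TRGV9"],
}
_J_GENES = {
    "IGH": ["IGHJ4", "IGHJ6"],
    "IGK": ["IGKJ1", "IGKJ4"],
    "IGL": ["IGLJ2", "IGLJ3"],
    "TRA": ["TRAJ33", "TRAJ49"],
    "TRB": ["TRBJ1-1", "TRBJ2-1"],
    "TRD": ["TRDJ1"],
    "TRG": ["TRGJ1", "TRGJ2"],
}

# one representative codon set per amino acid (no stop codons)
_CODONS = {
    "A": ["GCT", "GCC", "GCA"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC"], "K": ["AAA", "AAG"],
    "L": ["CTT", "CTC", "CTG"], "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC"], "Q": ["CAA", "CAG"], "R": ["CGT", "CGC"],
    "S": ["TCT", "TCC", "AGC"], "T": ["ACT", "ACC"], "V": ["GTT", "GTC"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_MIDDLE_AA = sorted(set(_CODONS) - {"C", "W"})
_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


def _random_cdr3(rng: np.random.Generator) -> str:
    """Random in-frame CDR3 (21-60 nt, C...F/W anchors, no stop codons)."""
    aa_len = int(rng.integers(7, 21))  # 21..60 nt
    aa = ["C"] + [_MIDDLE_AA[i] for i in rng.integers(0, len(_MIDDLE_AA), aa_len - 2)]
    aa.append("F" if rng.random() < 0.7 else "W")
    return "".join(
        _CODONS[a][int(rng.integers(0, len(_CODONS[a])))] for a in aa
    )


def _hamming_identity(a: str, b: str) -> float:
    return sum(1 for x, y in zip(a, b) if x == y) / len(a)


def _mutate(cdr3: str, n_mut: int, rng: np.random.Generator) -> str:
    """Substitute ``n_mut`` interior bases, never creating a stop codon."""
    seq = list(cdr3)
    # keep the anchor codons intact
    positions = list(range(3, len(seq) - 3))
    rng.shuffle(positions)
    done = 0
    for pos in positions:
        if done >= n_mut:
            break
        old = seq[pos]
        choices = [b for b in _BASES if b != old]
        rng.shuffle(choices)
        codon_start = (pos // 3) * 3
        for new in choices:
            seq[pos] = new
            codon = "".join(seq[codon_start : codon_start + 3])
            if codon not in _STOPS:
                done += 1
                break
            seq[pos] = old
    return "".join(seq)


# ---------------------------------------------------------------------------
# Latent layer: clone counts

def simulate_clone_counts(
    phenotype: str, locus: str, params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Clone read-count vector for one (sample, locus) draw.

    Total reads are negative-binomial with a phenotype-dependent mean; the
    clone count scales with reads and the phenotype's richness factor; reads
    are spread over clones with Zipf weights (phenotype-specific exponent).
    An empty vector means the chain was not detected.
    """
    mean = params.read_mean(phenotype, locus)
    shape = params.read_dispersion
    total = int(rng.negative_binomial(shape, shape / (shape + mean)))
    if total == 0:
        return np.array([], dtype=int)
    k = max(1, min(total, round(params.richness(phenotype) * total**0.7)))
    weights = np.arange(1, k + 1, dtype=float) ** -params.zipf(phenotype)
    weights /= weights.sum()
    counts = rng.multinomial(total, weights)
    return counts[counts > 0]


def expected_entropy(
    phenotype: str,
    locus: str,
    params: SimulationParams,
    n_draws: int = 10_000,
    seed: int = 12345,
) -> float:
    """Monte-Carlo expectation of realised Shannon entropy (detected draws only)."""
    from .metrics import shannon_entropy

    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_draws):
        counts = simulate_clone_counts(phenotype, locus, params, rng)
        if counts.size:
            values.append(shannon_entropy(counts))
    return float(np.mean(values)) if values else float("nan")


# ---------------------------------------------------------------------------
# Sequence layer

def simulate_repertoire(
    phenotype: str,
    locus: str,
    params: SimulationParams,
    rng: np.random.Generator,
    sample_id: str = "S",
) -> list[RearrangementRecord]:
    """Realise one (sample, locus) repertoire as rearrangement records.

    Each designed clone gets a random (V, J) pair and founder CDR3; extra
    within-clone variants carry at most floor((1 - threshold) * L) base
    substitutions from the founder, so single-linkage clustering at the
    locus threshold recovers exactly the designed clones.
    """
    counts = simulate_clone_counts(phenotype, locus, params, rng)
    threshold = params.threshold(locus)
    v_genes, j_genes = _V_GENES[locus], _J_GENES[locus]
    # founders of clones in the same (V, J, length) group must stay apart
    founders: dict[tuple[str, str, int], list[str]] = {}
    records: list[RearrangementRecord] = []
    seq_idx = 0
    for clone_idx, count in enumerate(counts):
        v = v_genes[int(rng.integers(0, len(v_genes)))] + "*01"
        j = j_genes[int(rng.integers(0, len(j_genes)))] + "*01"
        for _ in range(50):
            founder = _random_cdr3(rng)
            key = (v, j, len(founder))
            # cross-clone linkage impossible when founder identities stay
            # below 3*threshold - 2 (worst case with maximal within-clone drift)
            ceiling = max(3 * threshold - 2.0, 0.0)
            if all(
                _hamming_identity(founder, other) < ceiling
                for other in founders.get(key, [])
            ):
                break
        founders.setdefault(key, []).append(founder)
        length = len(founder)
        max_mut = int((1.0 - threshold) * length)
        n_variants = 1 + int(rng.poisson(params.variants_per_clone))
        n_variants = min(n_variants, int(count))
        if max_mut == 0:
            n_variants = 1
        # every variant gets >= 1 read; founder takes the remainder
        variant_reads = np.ones(n_variants, dtype=int)
        variant_reads[0] += int(count) - n_variants
        for vi in range(n_variants):
            if vi == 0:
                cdr3 = founder
            else:
                n_mut = min(int(rng.binomial(length, params.mutation_rate)) + 1, max_mut)
                cdr3 = _mutate(founder, n_mut, rng)
            aa = translate_cdr3(cdr3)
            is_complete = True
            out_of_frame = False
            if params.corruption_fraction and rng.random() < params.corruption_fraction:
                mode = int(rng.integers(0, 3))
                if mode == 0:  # premature stop
                    mid = (len(cdr3) // 6) * 3
                    cdr3 = cdr3[:mid] + "TAA" + cdr3[mid + 3 :]
                    aa = translate_cdr3(cdr3)
                elif mode == 1:  # frame shift
                    cdr3 = cdr3[1:]
                else:  # incomplete CDR3
                    is_complete = False
            records.append(
                RearrangementRecord(
                    sample_id=sample_id,
                    locus=locus,
                    v_call=v,
                    j_call=j,
                    cdr3_nt=cdr3,
                    cdr3_aa=aa if len(cdr3) % 3 == 0 else translate_cdr3(cdr3),
                    read_count=int(variant_reads[vi]),
                    is_complete=is_complete,
                    sequence_id=f"{sample_id}-{locus}-{clone_idx:04d}-{vi:02d}",
                    out_of_frame=out_of_frame,
                )
            )
            seq_idx += 1
    return records


# ---------------------------------------------------------------------------
# Clinical and expression layers

def simulate_clinical(
    sample_ids: list[str],
    phenotypes: list[str],
    params: SimulationParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Stage, survival time and event indicator per case.

    Survival times are exponential with log-hazard
    ``log(baseline) + phenotype_log_hr * [LSP] + stage_log_hr * (stage - II)``;
    censoring is independent (exponential + administrative cutoff).
    """
    stages = list(_STAGE_PROBS)
    stage_p = np.array(list(_STAGE_PROBS.values()))
    rows = []
    for sid, phenotype in zip(sample_ids, phenotypes):
        stage = stages[int(rng.choice(len(stages), p=stage_p))]
        stage_num = {"I": 1, "II": 2, "III": 3, "IV": 4}[stage]
        log_hazard = math.log(params.baseline_hazard) + params.stage_log_hr * (stage_num - 2)
        if phenotype == "LSP":
            log_hazard += params.phenotype_log_hr
        t_event = rng.exponential(1.0 / math.exp(log_hazard))
        t_censor = min(
            rng.exponential(1.0 / params.censor_rate) if params.censor_rate > 0 else np.inf,
            params.admin_censor_days,
        )
        event = int(t_event <= t_censor)
        rows.append(
            {
                "sample_id": sid,
                "phenotype": phenotype,
                "stage": stage,
                "vital_status": event,
                "os_days": float(min(t_event, t_censor)),
                "event": event,
            }
        )
    return pd.DataFrame(rows)


def simulate_expression(
    clinical: pd.DataFrame,
    chain_abundance: pd.DataFrame,  # samples x {BCR, TCR} total read counts
    params: SimulationParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Marker expression coupled to chain abundance, weaker for HSP."""
    from .stats import log2p1

    samples = list(clinical["sample_id"])
    phenotype = clinical.set_index("sample_id")["phenotype"]
    z = {}
    for chain_class in ("BCR", "TCR"):
        vals = log2p1(chain_abundance[chain_class].reindex(samples).to_numpy())
        sd = vals.std()
        z[chain_class] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
    rows = {}
    for gene, chain_class in [(g, "BCR") for g in B_CELL_MARKERS] + [
        (g, "TCR") for g in T_CELL_MARKERS
    ]:
        coupling = np.array(
            [
                params.coupling_lsp if phenotype[s] == "LSP" else params.coupling_hsp
                for s in samples
            ]
        )
        expr = (
            params.expression_base
            + coupling * z[chain_class]
            + rng.normal(0.0, params.expression_noise, len(samples))
        )
        rows[gene] = np.clip(expr, 0.0, None)
    return pd.DataFrame(rows, index=samples).T


# ---------------------------------------------------------------------------
# Cohort assembly

def entropy_table(params: SimulationParams, loci: tuple[str, ...] = LOCI) -> pd.DataFrame:
    """Fast latent-layer cohort: per-(sample, locus) metrics without sequences.

    Shares the clone-count generative layer with :func:`simulate_cohort`
    (sequence realisation adds nothing to abundance/entropy), so it is the
    layer of choice for calibration and power simulations.
    """
    from .metrics import clonality, shannon_entropy

    rng = np.random.default_rng(params.seed)
    rows = []
    phenotypes = ["LSP"] * params.n_lsp + ["HSP"] * params.n_hsp
    for i, phenotype in enumerate(phenotypes):
        sid = f"{phenotype}{i:03d}"
        for locus in loci:
            counts = simulate_clone_counts(phenotype, locus, params, rng)
            rows.append(
                {
                    "sample_id": sid,
                    "phenotype": phenotype,
                    "locus": locus,
                    "abundance": int(counts.sum()),
                    "n_clones": int(counts.size),
                    "entropy": shannon_entropy(counts) if counts.size else float("nan"),
                    "clonality": clonality(counts),
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(params: SimulationParams | None = None) -> SimulatedCohort:
    """Generate a complete cohort (repertoires, clinical, expression, truth)."""
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    phenotypes = ["LSP"] * params.n_lsp + ["HSP"] * params.n_hsp
    sample_ids = [f"{p}{i:03d}" for i, p in enumerate(phenotypes)]

    repertoires: dict[str, SampleRepertoire] = {}
    truth_samples = {}
    chain_abundance_rows = []
    for sid, phenotype in zip(sample_ids, phenotypes):
        records: list[RearrangementRecord] = []
        per_locus = {}
        for locus in LOCI:
            locus_records = simulate_repertoire(phenotype, locus, params, rng, sample_id=sid)
            records.extend(locus_records)
            per_locus[locus] = {
                "reads": int(sum(r.read_count for r in locus_records)),
                "n_records": len(locus_records),
            }
        total_reads = sum(r.read_count for r in records)
        library = int(
            max(
                rng.lognormal(params.library_log_mean, params.library_log_sigma),
                total_reads + 1,
            )
        )
        repertoires[sid] = SampleRepertoire(sid, records, library)
        truth_samples[sid] = {
            "phenotype": phenotype,
            "library_reads": library,
            "per_locus": per_locus,
        }
        chain_abundance_rows.append(
            {
                "sample_id": sid,
                "BCR": sum(per_locus[l]["reads"] for l in BCR_LOCI),
                "TCR": sum(per_locus[l]["reads"] for l in LOCI if l not in BCR_LOCI),
            }
        )

    clinical = simulate_clinical(sample_ids, phenotypes, params, rng)
    chain_abundance = pd.DataFrame(chain_abundance_rows).set_index("sample_id")
    expression = simulate_expression(clinical, chain_abundance, params, rng)

    truth = {
        "params": dataclasses.asdict(params),
        "samples": truth_samples,
    }
    return SimulatedCohort(
        repertoires=repertoires,
        clinical=clinical,
        expression=expression,
        truth=truth,
    )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, str]:
    """Write one AIRR TSV per sample plus clinical/expression/truth files."""
    outdir = Path(outdir)
    rep_dir = outdir / "repertoires"
    rep_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    library = {}
    for sid, rep in cohort.repertoires.items():
        path = rep_dir / f"{sid}.airr.tsv"
        write_rearrangements(rep, path)
        manifest[f"repertoire:{sid}"] = str(path)
        library[sid] = rep.library_reads
    clinical_path = outdir / "clinical.tsv"
    cohort.clinical.drop(columns=["event"], errors="ignore").to_csv(
        clinical_path, sep="\t", index=False
    )
    manifest["clinical"] = str(clinical_path)
    expr_path = outdir / "expression.tsv"
    cohort.expression.to_csv(expr_path, sep="\t", index_label="gene")
    manifest["expression"] = str(expr_path)
    library_path = outdir / "library_reads.tsv"
    pd.Series(library, name="library_reads").rename_axis("sample_id").to_csv(
        library_path, sep="\t"
    )
    manifest["library_reads"] = str(library_path)
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(cohort.truth, indent=1, default=str))
    manifest["truth"] = str(truth_path)
    return manifest
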