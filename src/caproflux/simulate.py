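"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all driven by one integer-seeded ``numpy`` Generator so a
given spec + seed reproduces byte-identical outputs:

* genomes: CDS features tiled with intergenic gaps over i.i.d. background
  sequence, with degenerate-consensus instances planted at known positions
  (optionally mutated).  Intergenic background is rejection-sampled so no
  background window reaches the scan threshold — planted-site truth is the
  complete hit set by construction.
* expression datasets: log-normal baseline means, negative-binomial counts
  per replicate, planted log2 effects of +/-Uniform(1.5, 5); the emitted
  differential table carries the *realized* fold-change estimate and an
  adjusted p-value from a conditional binomial (rate-ratio) test on summed
  counts with Benjamini-Hochberg correction.  This is a stand-in for a
  negative-binomial GLM fit, documented as such; the pipeline treats the
  columns as given.
* fermentation measurements: a true product spectrum plus Gaussian relative
  noise, truncated at zero, with the measured glucose and lactate
  fermentations available as built-in truths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import regulon
from .io import Feature, write_annotations, write_fasta

__all__ = [
    "GeneratorSpec",
    "SyntheticGenome",
    "SyntheticExpression",
    "REX_CONSENSUS",
    "LLDR_CONSENSUS",
    "EQ1_MEASURED",
    "EQ2_MEASURED",
    "gen_genome_with_sites",
    "gen_expression_dataset",
    "gen_fermentation_measurements",
]

REX_CONSENSUS = "TTGTTAANNNNTTAACAA"
LLDR_CONSENSUS = "TGGTNNNACCA"

# Measured species of the two fermentation equations (moles, as printed).
EQ1_MEASURED: Dict[str, float] = {"glucose": 6, "acetate": 2, "caproate": 4, "butyrate": 1}
EQ2_MEASURED: Dict[str, float] = {"lactate": 21, "acetate": 2, "caproate": 7, "butyrate": 1}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GeneratorSpec:
    """Sizes, rates and noise levels for all three generators."""

    seed: int = 0
    # genome generator
    n_cds: int = 40
    cds_length: Tuple[int, int] = (300, 900)
    gap_length: Tuple[int, int] = (80, 300)
    n_planted_sites: int = 10
    mutation_rate: float = 0.05  # per planted-site position; cap = ceil(rate * L)
    consensus: str = REX_CONSENSUS
    scan_threshold: float = 0.7  # background rejection uses the scanner itself
    gc: float = 0.5
    # expression generator
    n_genes: int = 500
    n_de: int = 50
    n_replicates: int = 3
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.2
    nb_dispersion: float = 0.05
    effect_range: Tuple[float, float] = (1.5, 5.0)
    # fermentation generator
    ferm_noise_sd: float = 0.05  # relative sd per species
    ferm_replicates: int = 3


@dataclass
class SyntheticGenome:
    sequence: str
    features: List[Feature]
    truth: pd.DataFrame  # site_id, seqid, start, end, strand, n_mismatches
    seqid: str = "synthetic_chrom"


@dataclass
class SyntheticExpression:
    counts: pd.DataFrame  # genes x (condition_replicate) columns
    table: pd.DataFrame  # gene_id, length, tpm_glucose, tpm_lactate, log2fc, padj, cog
    truth: pd.DataFrame  # gene_id, effect (planted log2 fold change)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def _realize_site(
    rng: np.random.Generator, consensus: str, mutation_rate: float
) -> Tuple[str, str, int]:
    """Instantiate a consensus: fill degenerate positions, mutate, orient."""
    site = [
        c if c in "ACGT" else rng.choice(list(regulon.IUPAC[c]))
        for c in consensus.upper()
    ]
    length = len(consensus)
    cap = math.ceil(mutation_rate * length)
    n_mut = min(int(rng.binomial(length, mutation_rate)), cap)
    for pos in rng.choice(length, size=n_mut, replace=False) if n_mut else []:
        alternatives = [b for b in "ACGT" if b != site[pos]]
        site[pos] = alternatives[int(rng.integers(3))]
    oriented = "".join(site)
    strand = "+" if rng.random() < 0.5 else "-"
    mismatches = regulon.hamming_to_consensus(oriented, consensus)
    if strand == "-":
        oriented = regulon.reverse_complement(oriented)
    return oriented, strand, mismatches


def _clean_gap(
    rng: np.random.Generator,
    motif: regulon.MotifModel,
    gap_len: int,
    planted: Optional[Tuple[str, int]],
    spec: GeneratorSpec,
    max_tries: int = 500,
) -> str:
    """A gap sequence whose only scan hits (if any) overlap the planted site."""
    for _ in range(max_tries):
        seq = _random_seq(rng, gap_len, spec.gc)
        if planted is not None:
            site, offset = planted
            seq = seq[:offset] + site + seq[offset + len(site) :]
            lo, hi = offset, offset + len(site)
        hits = regulon.scan_string(motif, seq, threshold=spec.scan_threshold)
        if planted is None:
            stray = hits
        else:
            stray = [h for h in hits if h[0] + motif.length <= lo or h[0] >= hi]
        if not stray:
            return seq
    raise RuntimeError("could not draw clean intergenic background; enlarge gaps")


def gen_genome_with_sites(
    spec: GeneratorSpec, out_dir: Optional[Path] = None
) -> SyntheticGenome:
    """A synthetic genome with CDS annotations and planted consensus sites.

    The layout is gap, CDS, gap, ..., CDS, gap (``n_cds + 1`` gaps); each of
    ``n_planted_sites`` distinct gaps receives one consensus instance on a
    random strand with at most ceil(mutation_rate * length) substitutions.
    Raises a sizing error when the sites cannot be packed.
    """
    rng = np.random.default_rng(spec.seed)
    motif = regulon.consensus_to_pwm(spec.consensus)
    length = motif.length
    n_gaps = spec.n_cds + 1
    lo, hi = spec.gap_length
    lo = max(lo, length + 4)  # every gap must be able to host a site
    gap_sizes = rng.integers(lo, max(hi, lo) + 1, size=n_gaps)
    cds_sizes = rng.integers(spec.cds_length[0], spec.cds_length[1] + 1, size=spec.n_cds)
    if spec.n_planted_sites * length >= int(gap_sizes.sum()):
        raise ValueError(
            "infeasible packing: planted sites exceed total intergenic length"
        )
    if spec.n_planted_sites > n_gaps:
        raise ValueError("infeasible packing: more planted sites than intergenic gaps")
    planted_gaps = set(
        rng.choice(n_gaps, size=spec.n_planted_sites, replace=False).tolist()
    )

    pieces: List[str] = []
    features: List[Feature] = []
    truth_rows: List[dict] = []
    seqid = "synthetic_chrom"
    pos = 0
    site_id = 0
    for i in range(n_gaps):
        gap_len = int(gap_sizes[i])
        planted = None
        meta = None
        if i in planted_gaps:
            oriented, strand, mism = _realize_site(rng, spec.consensus, spec.mutation_rate)
            offset = int(rng.integers(0, gap_len - length + 1))
            planted = (oriented, offset)
            meta = (strand, mism, offset)
        seq = _clean_gap(rng, motif, gap_len, planted, spec)
        if meta is not None:
            strand, mism, offset = meta
            truth_rows.append(
                {
                    "site_id": f"site_{site_id:04d}",
                    "seqid": seqid,
                    "start": pos + offset,
                    "end": pos + offset + length,
                    "strand": strand,
                    "n_mismatches": mism,
                }
            )
            site_id += 1
        pieces.append(seq)
        pos += gap_len
        if i < spec.n_cds:
            cds_len = int(cds_sizes[i])
            pieces.append(_random_seq(rng, cds_len, spec.gc))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"gene_{i:04d}"
            features.append(Feature(seqid, "CDS", pos, pos + cds_len, strand, gene_id))
            pos += cds_len

    genome = SyntheticGenome(
        sequence="".join(pieces),
        features=features,
        truth=pd.DataFrame(
            truth_rows,
            columns=["site_id", "seqid", "start", "end", "strand", "n_mismatches"],
        ),
        seqid=seqid,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(out_dir / "genome.fa", {seqid: genome.sequence})
        write_annotations(out_dir / "genome.gff3", features)
        genome.truth.to_csv(out_dir / "sites_truth.tsv", sep="\t", index=False)
    return genome


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float, n_reps: int
) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean, size=(n_reps, mean.size))
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p, size=(n_reps, mean.size))


def _binomial_rate_test(sum_a: np.ndarray, sum_b: np.ndarray, p0: float) -> np.ndarray:
    """Two-sided exact conditional binomial test on per-gene summed counts."""
    from scipy.stats import binom

    total = sum_a + sum_b
    with np.errstate(invalid="ignore"):
        cdf = binom.cdf(sum_b, total, p0)
        sf = binom.sf(sum_b - 1, total, p0)
    p = np.minimum(1.0, 2.0 * np.minimum(cdf, sf))
    p[total == 0] = 1.0
    return p


_COG_LETTERS = list("CDEFGHIJKLMNOPQTUV")


def gen_expression_dataset(
    spec: GeneratorSpec, out_dir: Optional[Path] = None
) -> SyntheticExpression:
    """Counts, a differential table, and the planted truth set."""
    if spec.n_de > spec.n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    gene_ids = [f"gene_{i:05d}" for i in range(n)]
    lengths = rng.integers(300, 3001, size=n)
    base = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, size=n)
    de_idx = rng.choice(n, size=spec.n_de, replace=False)
    effects = rng.uniform(*spec.effect_range, size=spec.n_de) * rng.choice(
        [-1.0, 1.0], size=spec.n_de
    )
    mean_glc = base
    mean_lac = base.copy()
    mean_lac[de_idx] = base[de_idx] * 2.0 ** effects

    counts_glc = _nb_counts(rng, mean_glc, spec.nb_dispersion, spec.n_replicates)
    counts_lac = _nb_counts(rng, mean_lac, spec.nb_dispersion, spec.n_replicates)

    from .expression import tpm_from_counts

    tpm_glc = np.vstack([tpm_from_counts(c, lengths) for c in counts_glc]).mean(axis=0)
    tpm_lac = np.vstack([tpm_from_counts(c, lengths) for c in counts_lac]).mean(axis=0)

    sum_glc = counts_glc.sum(axis=0).astype(float)
    sum_lac = counts_lac.sum(axis=0).astype(float)
    log2fc = np.log2((sum_lac + 0.5) / (sum_glc + 0.5))
    lib_glc, lib_lac = sum_glc.sum(), sum_lac.sum()
    p0 = lib_lac / (lib_glc + lib_lac) if (lib_glc + lib_lac) > 0 else 0.5
    pvals = _binomial_rate_test(sum_glc, sum_lac, p0)
    padj = multipletests(pvals, method="fdr_bh")[1]
    cog = rng.choice(_COG_LETTERS, size=n)
    cog = np.where(rng.random(n) < 0.1, "", cog)  # ~10% unannotated

    counts_cols = {
        f"glucose_rep{r + 1}": counts_glc[r] for r in range(spec.n_replicates)
    }
    counts_cols.update(
        {f"lactate_rep{r + 1}": counts_lac[r] for r in range(spec.n_replicates)}
    )
    counts = pd.DataFrame({"gene_id": gene_ids, **counts_cols})
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "length": lengths,
            "tpm_glucose": tpm_glc,
            "tpm_lactate": tpm_lac,
            "log2fc": log2fc,
            "padj": padj,
            "cog": cog,
        }
    )
    truth = pd.DataFrame(
        {"gene_id": [gene_ids[i] for i in de_idx], "effect": effects}
    ).sort_values("gene_id").reset_index(drop=True)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        counts.to_csv(out_dir / "counts.tsv", sep="\t", index=False)
        table.to_csv(out_dir / "expression_table.tsv", sep="\t", index=False)
        truth.to_csv(out_dir / "de_truth.tsv", sep="\t", index=False)
    return SyntheticExpression(counts=counts, table=table, truth=truth)


def gen_fermentation_measurements(
    spec: GeneratorSpec,
    true_spectrum: Mapping[str, float],
    out_path: Optional[Path] = None,
) -> pd.DataFrame:
    """Noisy replicate product spectra around a true spectrum.

    Gaussian noise with sd = ``ferm_noise_sd`` * |true value| per species,
    truncated at zero so no negative moles are ever emitted.
    """
    if spec.ferm_noise_sd < 0:
        raise ValueError("noise sd must be nonnegative")
    rng = np.random.default_rng(spec.seed)
    species = list(true_spectrum)
    truth = np.array([true_spectrum[s] for s in species], dtype=float)
    draws = rng.normal(
        loc=truth,
        scale=spec.ferm_noise_sd * np.abs(truth),
        size=(spec.ferm_replicates, len(species)),
    )
    draws = np.maximum(draws, 0.0)
    df = pd.DataFrame(draws, columns=species)
    df.insert(0, "replicate", [f"rep{i + 1}" for i in range(spec.ferm_replicates)])
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df
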